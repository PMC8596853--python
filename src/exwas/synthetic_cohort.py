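"""Seeded generators for a synthetic exome-sequencing cohort.

Every input the downstream pipeline consumes — genotypes with per-call read
evidence, functional annotations, phenotypes and covariates, a GWAS sentinel
landscape, per-gene carrier-count tables and imputation-accuracy curves — is
produced here with the statistical structure that large exome studies of
unrelated individuals exhibit: a rare-variant frequency spectrum dominated by
singletons, a consequence-class mix spanning synonymous through pLOF, per
genotype read depth and allele balance, and age-correlated somatic (CHIP-like)
variants with skewed variant allele fraction.

No linkage disequilibrium, phasing, relatedness or population structure is
modelled: samples and variants are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "PLOF_CLASSES",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_VOTE_DISTRIBUTION",
    "BetaMixture",
    "ReadEvidenceSpec",
    "CohortSpec",
    "TraitSpec",
    "GenotypeMatrix",
    "Cohort",
    "gen_cohort",
    "gen_phenotypes",
    "gen_gwas_landscape",
    "gen_carrier_table",
    "gen_carrier_count_table",
    "gen_accuracy_curve",
    "write_vcf",
    "read_vcf",
    "write_tsv",
    "read_tsv",
]

MISSING = -1  # dosage code for a no-call genotype

PLOF_CLASSES = frozenset(
    {"start_lost", "stop_gained", "stop_lost", "splice_donor",
     "splice_acceptor", "frameshift"}
)

# Consequence-class mix of the 12.3M coding variants in a 450k-exome study
# (proportions of: synonymous, missense, in-frame indel and the six pLOF
# subclasses). These defaults emulate the discovery-catalogue composition.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "synonymous": 3_457_173 / 12_326_144,
    "missense": 7_878_586 / 12_326_144,
    "inframe_indel": 75_096 / 12_326_144,
    "start_lost": 26_453 / 12_326_144,
    "stop_gained": 279_913 / 12_326_144,
    "stop_lost": 12_843 / 12_326_144,
    "splice_donor": 104_328 / 12_326_144,
    "splice_acceptor": 86_083 / 12_326_144,
    "frameshift": 405_669 / 12_326_144,
}

# Deleteriousness votes (0-5 algorithms) for missense variants: 19.4% with no
# vote (likely benign), 22.7% with all five (likely deleterious), the
# remainder spread over 1-4 votes.
_p0 = 1_532_129 / 7_878_586
_p5 = 1_789_828 / 7_878_586
_pmid = (1.0 - _p0 - _p5) / 4.0
DEFAULT_VOTE_DISTRIBUTION: tuple[float, ...] = (_p0, _pmid, _pmid, _pmid, _pmid, _p5)

# Overall fraction of discovered coding variants with MAC = 1 (singletons).
DEFAULT_SINGLETON_MASS = 0.4686

INDEL_CLASSES = frozenset({"inframe_indel", "frameshift"})


class ConfigurationError(ValueError):
    """Raised when a generator spec is internally inconsistent."""


class CalibrationError(RuntimeError):
    """Raised when the intercept cannot be calibrated to the target prevalence."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaMixture:
    """Mixture of beta distributions over per-gene carrier frequencies."""

    weights: tuple[float, ...]
    alphas: tuple[float, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.alphas) == len(self.betas)):
            raise ConfigurationError("mixture weight/shape lengths differ")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("mixture weights must be non-negative")
        if any(a <= 0 for a in self.alphas) or any(b <= 0 for b in self.betas):
            raise ConfigurationError("beta shapes must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        a = np.asarray(self.alphas)[comp]
        b = np.asarray(self.betas)[comp]
        return rng.beta(a, b)


@dataclass(frozen=True)
class ReadEvidenceSpec:
    """Per-genotype read depth / allele-balance model.

    Depth is negative-binomial with the given mean and dispersion (variance
    ``mean + mean**2 / dispersion``); alternate-allele depth is binomial given
    depth, centred at `het_ab` for germline heterozygotes.  A configurable
    fraction of variants is somatic: their carriers have an extreme variant
    allele fraction (VAF parameter outside [0.35, 0.65]) and carrier
    probability logistic in age.
    """

    mean_depth: float = 35.0
    depth_dispersion: float = 8.0
    het_ab: float = 0.5
    somatic_fraction: float = 0.0
    somatic_vaf: float = 0.2
    somatic_age_slope: float = 0.12      # per year, log-odds of carrying
    somatic_age_midpoint: float = 75.0   # age at which carrier prob is half max
    somatic_max_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("depth parameters must be positive")
        if not 0.0 <= self.somatic_fraction <= 1.0:
            raise ConfigurationError("somatic_fraction must be in [0, 1]")
        if 0.35 <= self.somatic_vaf <= 0.65:
            raise ConfigurationError(
                "somatic VAF parameter must lie outside [0.35, 0.65]")


@dataclass(frozen=True)
class CohortSpec:
    """Shape and composition of a synthetic exome cohort.

    `eaf_spectrum` is a (singleton_mass, log10_maf_lo, log10_maf_hi) triple:
    with probability `singleton_mass` a variant is a singleton (one carrier,
    frequency 1/(2N)); otherwise its allele frequency is log-uniform on
    [10**lo, 10**hi].
    """

    n_samples: int = 1000
    n_genes: int = 20
    variants_per_gene: int = 10
    singleton_mass: float = DEFAULT_SINGLETON_MASS
    log10_maf_range: tuple[float, float] = (-3.5, -2.0)
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    vote_distribution: tuple[float, ...] = DEFAULT_VOTE_DISTRIBUTION
    read_evidence: ReadEvidenceSpec = field(default_factory=ReadEvidenceSpec)
    gene_length: int = 10_000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_genes < 1 or self.variants_per_gene < 1:
            raise ConfigurationError("need at least one gene and one variant")
        unknown = set(self.class_mix) - set(DEFAULT_CLASS_MIX)
        if unknown:
            raise ConfigurationError(f"unknown consequence classes: {sorted(unknown)}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix proportions must sum to 1")
        if abs(sum(self.vote_distribution) - 1.0) > 1e-9 or len(self.vote_distribution) != 6:
            raise ConfigurationError("vote_distribution must be 6 probabilities summing to 1")
        if not 0.0 <= self.singleton_mass <= 1.0:
            raise ConfigurationError("singleton_mass must be in [0, 1]")


@dataclass(frozen=True)
class TraitSpec:
    """Generative model for one phenotype.

    Binary traits follow ``logit(p) = mu + G beta + covariate terms`` with
    ``mu`` calibrated so the realized mean of p equals the prevalence `K`;
    quantitative traits are Gaussian around the genetic + covariate mean with
    unit residual variance.  Effect-map keys may be variant ids (effect of
    per-variant dosage) or gene ids (effect of the collapsed protein-altering
    burden dosage in that gene).
    """

    kind: str = "quantitative"            # "binary" | "quantitative"
    prevalence: float | None = None       # binary only
    effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    # recognised covariate keys: age, age2, sex, age_sex

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ConfigurationError("trait kind must be binary or quantitative")
        if self.kind == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ConfigurationError("binary trait requires 0 < prevalence < 1")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """samples x variants allele dosages with per-call read evidence.

    `dosage` is int8 with -1 for missing; `dp` and `ad` are per-call total
    and alternate-allele read depths (same shape).
    """

    dosage: np.ndarray
    samples: list[str]
    variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt, variant_type, gene_id
    dp: np.ndarray | None = None
    ad: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage.copy(),
            samples=list(self.samples),
            variants=self.variants.copy(),
            dp=None if self.dp is None else self.dp.copy(),
            ad=None if self.ad is None else self.ad.copy(),
        )


@dataclass
class Cohort:
    """Bundle returned by :func:`gen_cohort`."""

    genotypes: GenotypeMatrix
    annotations: pd.DataFrame   # variant_id, gene_id, consequence, deleterious_votes
    genes: pd.DataFrame         # gene_id, chrom, start, end (1-based closed)
    demographics: pd.DataFrame  # sample_id, age, sex (0 female / 1 male)
    somatic_variants: list[str]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _draw_consequences(spec: CohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    classes = list(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    return np.asarray(classes)[rng.choice(len(classes), size=n, p=probs)]


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate genotypes, annotations, gene models and read evidence.

    Deterministic for a fixed spec (the seed lives in the spec).  Every
    variant has MAC >= 1: singleton variants get exactly one heterozygous
    carrier; non-singleton variants with no sampled carrier are given one.
    """
    rng = np.random.default_rng(spec.seed)
    n, g, vpg = spec.n_samples, spec.n_genes, spec.variants_per_gene
    n_var = g * vpg

    samples = [f"S{i:06d}" for i in range(n)]
    ages = rng.integers(40, 70, size=n)
    sex = rng.integers(0, 2, size=n)
    demographics = pd.DataFrame({"sample_id": samples, "age": ages, "sex": sex})

    gene_ids = [f"G{j:05d}" for j in range(g)]
    starts = 1 + np.arange(g) * (spec.gene_length * 2)
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": spec.chrom,
        "start": starts,
        "end": starts + spec.gene_length - 1,
    })

    consequences = _draw_consequences(spec, n_var, rng)
    is_indel = np.isin(consequences, list(INDEL_CLASSES))
    votes = np.full(n_var, -1)
    is_mis = consequences == "missense"
    votes[is_mis] = rng.choice(6, size=int(is_mis.sum()),
                               p=np.asarray(spec.vote_distribution))

    # Somatic variants: chosen among SNV-like variants, carriers assigned by age
    somatic = np.zeros(n_var, dtype=bool)
    re_spec = spec.read_evidence
    if re_spec.somatic_fraction > 0:
        candidates = np.flatnonzero(~is_indel)
        k = int(round(re_spec.somatic_fraction * n_var))
        if k > 0 and len(candidates) > 0:
            somatic[rng.choice(candidates, size=min(k, len(candidates)),
                               replace=False)] = True

    is_singleton = rng.random(n_var) < spec.singleton_mass
    lo, hi = spec.log10_maf_range
    maf = 10.0 ** rng.uniform(lo, hi, size=n_var)

    dosage = np.zeros((n, n_var), dtype=np.int8)
    for v in range(n_var):
        if somatic[v]:
            page = re_spec.somatic_max_prob * expit(
                re_spec.somatic_age_slope * (ages - re_spec.somatic_age_midpoint))
            carrier = rng.random(n) < page
            if not carrier.any():
                carrier[np.argmax(ages)] = True  # MAC >= 1
            dosage[carrier, v] = 1
        elif is_singleton[v]:
            dosage[rng.integers(n), v] = 1
        else:
            # non-singleton stratum: keep >= 2 carrier samples so the realized
            # singleton fraction tracks the requested point mass at any n
            d = rng.binomial(2, maf[v], size=n).astype(np.int8)
            while (d > 0).sum() < 2:
                d[rng.integers(n)] = 1
            dosage[:, v] = d

    gene_of = np.repeat(np.arange(g), vpg)
    offsets = rng.integers(0, spec.gene_length, size=n_var)
    # ensure unique, sorted positions within each gene
    pos = np.empty(n_var, dtype=np.int64)
    for j in range(g):
        idx = np.flatnonzero(gene_of == j)
        off = np.sort(np.unique(offsets[idx]))
        while len(off) < len(idx):
            off = np.sort(np.unique(np.concatenate(
                [off, rng.integers(0, spec.gene_length, size=len(idx) - len(off))])))
        pos[idx] = starts[j] + off[: len(idx)]

    ref = np.where(is_indel, "AT", "A")
    alt = np.where(is_indel, "A", "G")
    variants = pd.DataFrame({
        "variant_id": [f"{spec.chrom}:{p}:{r}:{a}" for p, r, a in zip(pos, ref, alt)],
        "chrom": spec.chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "variant_type": np.where(is_indel, "indel", "SNV"),
        "gene_id": [gene_ids[j] for j in gene_of],
    })

    # Read evidence: NB depth, binomial alt depth given depth
    p_nb = re_spec.depth_dispersion / (re_spec.depth_dispersion + re_spec.mean_depth)
    dp = rng.negative_binomial(re_spec.depth_dispersion, p_nb, size=(n, n_var))
    ab = np.where(dosage == 1, re_spec.het_ab, np.where(dosage == 2, 1.0, 0.0))
    ab = np.where((dosage == 1) & somatic[None, :], re_spec.somatic_vaf, ab)
    ad = rng.binomial(dp, ab)

    annotations = pd.DataFrame({
        "variant_id": variants["variant_id"],
        "gene_id": variants["gene_id"],
        "consequence": consequences,
        "deleterious_votes": votes,
    })

    gm = GenotypeMatrix(dosage=dosage, samples=samples, variants=variants,
                        dp=dp, ad=ad)
    return Cohort(
        genotypes=gm,
        annotations=annotations,
        genes=genes,
        demographics=demographics,
        somatic_variants=list(variants.loc[somatic, "variant_id"]),
    )


# ---------------------------------------------------------------------------
# Phenotype generation
# ---------------------------------------------------------------------------

def _covariate_table(demographics: pd.DataFrame) -> pd.DataFrame:
    age = demographics["age"].to_numpy(dtype=float)
    sex = demographics["sex"].to_numpy(dtype=float)
    return pd.DataFrame({
        "sample_id": demographics["sample_id"],
        "age": age,
        "age2": age ** 2,
        "sex": sex,
        "age_sex": age * sex,
    })


def _genetic_score(cohort: Cohort, effects: dict[str, float]) -> np.ndarray:
    """G beta over the effect map; gene keys use the collapsed burden dosage
    (max per-variant dosage over the gene's protein-altering variants)."""
    gm = cohort.genotypes
    score = np.zeros(gm.n_samples)
    vid_index = pd.Index(gm.variants["variant_id"])
    anno = cohort.annotations
    for key, beta in effects.items():
        if key in vid_index:
            v = vid_index.get_loc(key)
            score += beta * np.maximum(gm.dosage[:, v], 0)
        elif (anno["gene_id"] == key).any():
            damaging = anno["consequence"].isin(PLOF_CLASSES) | (
                (anno["consequence"] == "missense") & (anno["deleterious_votes"] == 5))
            vids = anno.loc[(anno["gene_id"] == key) & damaging, "variant_id"]
            cols = [vid_index.get_loc(v) for v in vids]
            if cols:
                burden = np.maximum(gm.dosage[:, cols], 0).max(axis=1)
                score += beta * burden
        else:
            raise ConfigurationError(f"effect key {key!r} matches no variant or gene")
    return score


def calibrate_intercept(eta: np.ndarray, prevalence: float, tol: float = 1e-8) -> float:
    """Solve mean(expit(mu + eta)) = prevalence for mu by root finding."""

    def f(mu: float) -> float:
        return float(np.mean(expit(mu + eta))) - prevalence

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"prevalence {prevalence} not achievable given the linear predictor")
    return float(brentq(f, lo, hi, xtol=tol))


def gen_phenotypes(cohort: Cohort, trait: TraitSpec, seed: int
                   ) -> tuple[pd.Series, pd.DataFrame]:
    """Generate a phenotype vector and a covariate table for a cohort."""
    rng = np.random.default_rng(seed)
    covars = _covariate_table(cohort.demographics)
    eta = _genetic_score(cohort, trait.effects)
    for key, coef in trait.covariate_effects.items():
        if key not in ("age", "age2", "sex", "age_sex"):
            raise ConfigurationError(f"unknown covariate {key!r}")
        eta = eta + coef * covars[key].to_numpy()

    if trait.kind == "binary":
        mu = calibrate_intercept(eta, trait.prevalence)
        p = expit(mu + eta)
        y = rng.binomial(1, p).astype(np.int64)
    else:
        y = eta + rng.standard_normal(len(eta))
    return pd.Series(y, index=covars["sample_id"].to_numpy(), name="trait"), covars


# ---------------------------------------------------------------------------
# GWAS sentinel landscape
# ---------------------------------------------------------------------------

def gen_gwas_landscape(
    n_traits: int,
    n_signals_per_trait: int,
    genome_length: int,
    n_genes: int = 500,
    n_causal_per_trait: int = 10,
    density_ratio: float = 1.0,
    window: int = 1_000_000,
    chrom: str = "1",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a GWAS-signal table, a gene-model table and truth labels.

    Genes are tiled uniformly over a single synthetic chromosome; per trait,
    `n_signals_per_trait` sentinels are placed uniformly at random and
    `n_causal_per_trait` causal genes are drawn without replacement with
    sampling weight `density_ratio` for genes within `window` bp of any of
    that trait's sentinels and weight 1 elsewhere.  Truth labels record, per
    trait, each causal gene and whether it lies within the window.

    Returns ``(signals, genes, truth)``.
    """
    if n_genes < n_causal_per_trait:
        raise ConfigurationError("more causal genes requested than genes exist")
    rng = np.random.default_rng(seed)
    gene_len = max(1, genome_length // (2 * n_genes))
    starts = np.linspace(1, genome_length - gene_len, n_genes).astype(np.int64)
    genes = pd.DataFrame({
        "gene_id": [f"G{j:05d}" for j in range(n_genes)],
        "chrom": chrom,
        "start": starts,
        "end": starts + gene_len - 1,
    })
    mid = (genes["start"] + genes["end"]).to_numpy() // 2

    sig_rows, truth_rows = [], []
    for t in range(n_traits):
        trait_id = f"T{t:03d}"
        pos = np.sort(rng.integers(1, genome_length + 1, size=n_signals_per_trait))
        pvals = 10.0 ** -rng.uniform(8, 50, size=n_signals_per_trait)
        for p_, pv in zip(pos, pvals):
            sig_rows.append((trait_id, chrom, int(p_), float(pv)))
        near = np.zeros(n_genes, dtype=bool)
        for p_ in pos:
            near |= np.abs(mid - p_) <= window
        w = np.where(near, density_ratio, 1.0)
        w = w / w.sum()
        causal = rng.choice(n_genes, size=n_causal_per_trait, replace=False, p=w)
        for j in causal:
            truth_rows.append((trait_id, genes["gene_id"].iloc[j], bool(near[j])))

    signals = pd.DataFrame(sig_rows, columns=["trait_id", "chrom", "pos", "pvalue"])
    truth = pd.DataFrame(truth_rows, columns=["trait_id", "gene_id", "near_signal"])
    return signals, genes, truth


# ---------------------------------------------------------------------------
# Carrier-count tables & accuracy curves
# ---------------------------------------------------------------------------

def gen_carrier_table(mixture: BetaMixture, n_genes: int, n_samples: int,
                      seed: int = 0) -> pd.DataFrame:
    """Per-gene carrier counts for one carrier process.

    Carrier frequency is drawn per gene from the beta mixture; the carrier
    count is binomial given that frequency and the cohort size.
    """
    if n_genes < 1 or n_samples < 1:
        raise ConfigurationError("n_genes and n_samples must be positive")
    rng = np.random.default_rng(seed)
    freq = mixture.sample(n_genes, rng)
    counts = rng.binomial(n_samples, freq)
    return pd.DataFrame({
        "gene_id": [f"G{j:05d}" for j in range(n_genes)],
        "carrier_count": counts,
    })


def gen_carrier_count_table(het_mixture: BetaMixture, hom_mixture: BetaMixture,
                            n_genes: int, n_samples: int, seed: int = 0
                            ) -> pd.DataFrame:
    """Het + hom carrier-count table (independent processes), for projections."""
    het = gen_carrier_table(het_mixture, n_genes, n_samples, seed)
    hom = gen_carrier_table(hom_mixture, n_genes, n_samples, seed + 1)
    return pd.DataFrame({
        "gene_id": het["gene_id"],
        "het_carriers": het["carrier_count"],
        "hom_carriers": hom["carrier_count"],
    })


def gen_accuracy_curve(a: float, b: float, c: float, panel_sizes,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """(n, r2) points from r2 = c / (1 + exp(-(a + b log n))) + noise."""
    if not 0.0 < c <= 1.0:
        raise ConfigurationError("asymptote c must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = np.asarray(panel_sizes, dtype=float)
    r2 = c * expit(a + b * np.log(n))
    if noise_sd > 0:
        r2 = r2 + rng.normal(0.0, noise_sd, size=len(n))
    return pd.DataFrame({"n": n, "r2": np.clip(r2, 0.0, 1.0)})


# ---------------------------------------------------------------------------
# I/O: VCF (with DP/AD), TSV
# ---------------------------------------------------------------------------

_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write genotypes with per-call DP and AD to an uncompressed VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths (ref, alt)">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">')
    header.add_line('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">')
    for chrom in gm.variants["chrom"].unique():
        header.contigs.add(str(chrom))
    for s in gm.samples:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as out:
        for v in range(gm.n_variants):
            row = gm.variants.iloc[v]
            rec = out.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]), id=row["variant_id"])
            rec.info["GENE"] = str(row["gene_id"])
            rec.info["VT"] = str(row["variant_type"])
            for i, s in enumerate(gm.samples):
                call = rec.samples[s]
                call["GT"] = _GT[int(gm.dosage[i, v])]
                if gm.dp is not None:
                    dp = int(gm.dp[i, v])
                    ad = int(gm.ad[i, v])
                    call["DP"] = dp
                    call["AD"] = (dp - ad, ad)
            out.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF written by :func:`write_vcf` back into a GenotypeMatrix."""
    import pysam

    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        rows, dosages, dps, ads = [], [], [], []
        for rec in vf:
            rows.append({
                "variant_id": rec.id,
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "variant_type": rec.info.get("VT", "SNV"),
                "gene_id": rec.info.get("GENE", ""),
            })
            dos, dp_row, ad_row = [], [], []
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or gt[0] is None:
                    dos.append(MISSING)
                else:
                    dos.append(int(gt[0] or 0) + int(gt[1] or 0))
                dp_row.append(call.get("DP") or 0)
                ad = call.get("AD")
                ad_row.append(0 if ad is None or ad[1] is None else int(ad[1]))
            dosages.append(dos)
            dps.append(dp_row)
            ads.append(ad_row)
    variants = pd.DataFrame(rows)
    return GenotypeMatrix(
        dosage=np.asarray(dosages, dtype=np.int8).T,
        samples=samples,
        variants=variants,
        dp=np.asarray(dps, dtype=np.int64).T,
        ad=np.asarray(ads, dtype=np.int64).T,
    )


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
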