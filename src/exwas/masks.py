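"""Functional tiers and gene-burden mask construction.

Rare protein-altering variants are collapsed per gene into a pseudo-genotype:
samples homozygous reference at every aggregated variant stay 0, carriers of
any aggregated variant are heterozygous (1), and only minor-allele homozygotes
at some aggregated variant are coded 2.  Genotypes are unphased, so compound
heterozygotes count as heterozygous.  Two class sets are used — M1 (pLOF only)
and M3 (pLOF + likely-deleterious missense, i.e. missense called deleterious
by all five prediction algorithms) — each crossed with five frequency bins
(MAF <= 1%, 0.1%, 0.01%, 0.001%, and singletons only).  Burdens (and single
variants) with minor allele count below 5 are not tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import MISSING, PLOF_CLASSES, GenotypeMatrix

__all__ = [
    "MIN_MAC",
    "FREQUENCY_BINS",
    "MaskSpec",
    "classify_missense",
    "mask_classes",
    "select_mask_variants",
    "collapse_burden",
    "burden_mac_filter",
    "encode_chrx_dosage",
    "build_burden_matrix",
]

MIN_MAC = 5

# bin label -> MAF ceiling; "singleton" is carrier-count based, not frequency
FREQUENCY_BINS: dict[str, float | None] = {
    "1%": 0.01,
    "0.1%": 0.001,
    "0.01%": 0.0001,
    "0.001%": 0.00001,
    "singleton": None,
}

VALID_CONSEQUENCES = PLOF_CLASSES | {"synonymous", "missense", "inframe_indel"}


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class MaskSpec:
    """One burden mask: class set M1 (pLOF) or M3 (pLOF + likely-deleterious
    missense) crossed with one frequency bin."""

    class_set: str       # "M1" | "M3"
    frequency_bin: str   # key of FREQUENCY_BINS

    def __post_init__(self) -> None:
        if self.class_set not in ("M1", "M3"):
            raise InputError(f"unknown class set {self.class_set!r}")
        if self.frequency_bin not in FREQUENCY_BINS:
            raise InputError(f"unknown frequency bin {self.frequency_bin!r}")


def classify_missense(deleterious_votes: int) -> str:
    """Tier a missense variant by its 0-5 deleteriousness votes."""
    if not 0 <= int(deleterious_votes) <= 5:
        raise InputError("deleterious votes must be in 0..5")
    if deleterious_votes == 5:
        return "likely_deleterious"
    if deleterious_votes >= 1:
        return "possibly_deleterious"
    return "likely_benign"


def mask_classes(annotations: pd.DataFrame, class_set: str) -> np.ndarray:
    """Boolean mask over annotation rows matching the class set."""
    plof = annotations["consequence"].isin(PLOF_CLASSES).to_numpy()
    if class_set == "M1":
        return plof
    deleterious = (
        (annotations["consequence"] == "missense")
        & (annotations["deleterious_votes"] == 5)
    ).to_numpy()
    return plof | deleterious


def singleton_variants(gm: GenotypeMatrix) -> np.ndarray:
    """Variants carried by exactly one sample (one het, or one hom-alt with
    no other carrier)."""
    carriers = (gm.dosage > 0).sum(axis=0)
    return carriers == 1


def select_mask_variants(
    gm: GenotypeMatrix,
    annotations: pd.DataFrame,
    stats: pd.DataFrame,
    mask: MaskSpec,
    gene_id: str | None = None,
) -> list[str]:
    """Variant ids matching the mask's class set and frequency bin.

    `stats` is the post-QC site-stats table (from ``variant_qc.site_stats``);
    in-sample MAF is used for bin assignment.  The singleton bin is defined by
    carrier count, not frequency.
    """
    anno = annotations.set_index("variant_id")
    vids = gm.variants["variant_id"]
    cls_ok = pd.Series(
        mask_classes(anno.loc[vids].reset_index(), mask.class_set), index=vids)
    ceiling = FREQUENCY_BINS[mask.frequency_bin]
    if ceiling is None:
        freq_ok = pd.Series(singleton_variants(gm), index=vids)
    else:
        maf = stats.set_index("variant_id").loc[vids, "maf"]
        freq_ok = maf <= ceiling
    ok = cls_ok & freq_ok
    if gene_id is not None:
        ok &= (gm.variants.set_index("variant_id")["gene_id"] == gene_id)
    return list(vids[ok.to_numpy()])


def collapse_burden(dosage_subset: np.ndarray, missing_as_ref: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a samples x subset-variants dosage block into per-sample
    burden dosages.

    Returns ``(burden, n_contributing)`` where burden is 0 (hom-ref at every
    subset variant), 2 (hom-alt at >= 1 subset variant) or 1 (het at >= 1,
    no hom-alt; unphased compound hets collapse to 1), and n_contributing is
    the per-sample count of non-missing contributing calls.
    """
    d = np.asarray(dosage_subset)
    if d.ndim == 1:
        d = d[:, None]
    if d.shape[1] == 0:
        raise InputError("cannot collapse an empty variant subset")
    nonmiss = d != MISSING
    n_contributing = nonmiss.sum(axis=1)
    if not missing_as_ref and (~nonmiss).any():
        eff = np.where(nonmiss, d, MISSING)
        burden = np.where((eff == MISSING).all(axis=1), MISSING,
                          np.where(nonmiss, d, 0).max(axis=1))
        return burden.astype(np.int8), n_contributing
    burden = np.where(nonmiss, d, 0).max(axis=1)
    return burden.astype(np.int8), n_contributing


def burden_mac_filter(burden: np.ndarray, min_mac: int = MIN_MAC) -> bool:
    """Keep (True) iff the collapsed minor-allele count is >= 5."""
    b = np.asarray(burden)
    b = b[b != MISSING]
    mac = int(np.minimum(b.sum(), 2 * len(b) - b.sum()))
    return mac >= min_mac


def encode_chrx_dosage(dosage: np.ndarray, is_male: np.ndarray) -> np.ndarray:
    """Dosage compensation for non-pseudoautosomal chrX: hom-ref males 0,
    hemizygous (any alt call) males 2; females unchanged."""
    d = np.asarray(dosage).copy()
    male = np.asarray(is_male, dtype=bool)
    carrier = (d > 0) & male[..., None] if d.ndim == 2 else (d > 0) & male
    d[carrier] = 2
    return d


def build_burden_matrix(
    gm: GenotypeMatrix,
    annotations: pd.DataFrame,
    stats: pd.DataFrame,
    mask: MaskSpec,
    apply_mac_filter: bool = True,
) -> pd.DataFrame:
    """Genes x samples burden-dosage table for one mask.

    Genes with an empty variant subset, or failing the MAC >= 5 rule when
    `apply_mac_filter` is set, are omitted.
    """
    vid_index = pd.Index(gm.variants["variant_id"])
    rows, index = [], []
    for gene_id, sub in gm.variants.groupby("gene_id", sort=True):
        vids = select_mask_variants(gm, annotations, stats, mask, gene_id=gene_id)
        if not vids:
            continue
        cols = [vid_index.get_loc(v) for v in vids]
        burden, _ = collapse_burden(gm.dosage[:, cols])
        if apply_mac_filter and not burden_mac_filter(burden):
            continue
        rows.append(burden)
        index.append(gene_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="gene_id"),
                        columns=gm.samples)
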