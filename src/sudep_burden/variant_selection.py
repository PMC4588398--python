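"""Individual-level QC metrics and genome-wide variant selection.

The genome-wide burden stage keeps variants that are (a) protein-changing,
(b) rare in a reference population (MAF <= 0.5% by default, boundary
inclusive), (c) observed at least once in the joint call set, and (d)
sequenced in strictly more than 80% of each of the three groups
separately.  The last rule is a batch correction: it removes sites whose
capture-kit coverage differs systematically between cohorts, which would
otherwise bias per-individual burden scores.

The 80% cut-off itself can be audited with
:func:`sweep_group_fraction_threshold`, which recomputes all per-individual
burden scores over a grid of thresholds and reports the coefficient of
variation of the scores at each — the rationale being that a threshold
admitting batch-structured missingness inflates between-sample score
spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GROUPS, MISSING, GenotypeMatrix, VariantRecord

PROTEIN_CHANGING_DEFAULT = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "canonical_splice"}
)


@dataclass
class SelectionConfig:
    maf_threshold: float = 0.005
    group_fraction_threshold: float = 0.80
    protein_changing_classes: frozenset[str] = PROTEIN_CHANGING_DEFAULT

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "group_fraction_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        self.protein_changing_classes = frozenset(self.protein_changing_classes)


def is_protein_changing(record: VariantRecord,
                        config: SelectionConfig | None = None) -> bool:
    classes = (config or SelectionConfig()).protein_changing_classes
    return record.func_class in classes


def passes_rare_filter(record: VariantRecord,
                       config: SelectionConfig | None = None) -> bool:
    """Rarity filter on the reference-population MAF; boundary inclusive."""
    threshold = (config or SelectionConfig()).maf_threshold
    return record.ref_maf <= threshold


def group_sequenced_fraction(matrix: GenotypeMatrix, variant: str,
                             group: str) -> float:
    """Fraction of the group with a called (non-missing) genotype."""
    mask = matrix.group_mask(group)
    if not mask.any():
        raise ValueError(f"group {group!r} is empty")
    col = matrix.geno[mask, matrix.variant_index(variant)]
    return float((col != MISSING).mean())


def _group_fractions(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-variant sequenced fraction for each group; shape 3 x n_variants."""
    out = np.empty((len(GROUPS), matrix.n_variants))
    called = matrix.geno != MISSING
    for gi, g in enumerate(GROUPS):
        mask = matrix.group_mask(g)
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        out[gi] = called[mask].mean(axis=0)
    return out


def select_genomewide_variants(
    matrix: GenotypeMatrix,
    annotations: dict[str, VariantRecord],
    config: SelectionConfig | None = None,
) -> set[str]:
    """Apply the four genome-wide selection rules; returns surviving keys.

    The sequenced-fraction rule is strict (> threshold) and is applied to
    each of the three groups separately, so a variant under-covered in any
    one cohort is dropped for everyone.
    """
    config = config or SelectionConfig()
    recs = [annotations[k] for k in matrix.variants]
    protein = np.array([is_protein_changing(r, config) for r in recs])
    rare = np.array([passes_rare_filter(r, config) for r in recs])
    observed = (matrix.geno > 0).any(axis=0)
    fractions = _group_fractions(matrix)
    covered = (fractions > config.group_fraction_threshold).all(axis=0)
    keep = protein & rare & observed & covered
    return {k for k, ok in zip(matrix.variants, keep) if ok}


# ---------------------------------------------------------------------------
# Individual-level QC
# ---------------------------------------------------------------------------

def individual_qc(matrix: GenotypeMatrix, k_mad: float = 4.0) -> pd.DataFrame:
    """Per-sample call rate, singleton count and heterozygosity, with
    robust outlier flags.

    A singleton is a variant whose total non-reference allele count across
    the whole call set is exactly 1.  A sample is flagged when any of the
    three metrics deviates from the cohort median by more than ``k_mad``
    median absolute deviations (a metric with zero MAD is skipped), or when
    it has no called genotypes at all.
    """
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise ValueError("matrix must be non-empty")
    geno = matrix.geno
    called = geno != MISSING
    nonref = np.where(called, geno, 0)

    call_rate = called.mean(axis=1)
    total_alleles = nonref.sum(axis=0)
    singleton_cols = total_alleles == 1
    singleton_count = (nonref[:, singleton_cols] > 0).sum(axis=1)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_called > 0, (geno == 1).sum(axis=1) / n_called, 0.0)

    flags = np.zeros(matrix.n_samples, dtype=bool)
    for metric in (call_rate, singleton_count.astype(float), het_rate):
        med = np.median(metric)
        mad = np.median(np.abs(metric - med))
        if mad > 0:
            flags |= np.abs(metric - med) > k_mad * mad
    flags |= n_called == 0

    return pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "group": matrix.groups,
            "call_rate": call_rate,
            "singleton_count": singleton_count,
            "het_rate": het_rate,
            "outlier_flag": flags,
        }
    )


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

def sweep_group_fraction_threshold(
    matrix: GenotypeMatrix,
    annotations: dict[str, VariantRecord],
    thresholds=(0.5, 0.6, 0.7, 0.8, 0.9),
    config: SelectionConfig | None = None,
    variability: str = "cv",
) -> pd.DataFrame:
    """Coefficient of variation of per-individual burden scores per
    sequenced-fraction threshold.

    Returns a table with columns ``threshold``, ``n_variants``,
    ``variability`` (NaN when no variant survives) and ``is_argmin``.
    ``variability="var"`` switches to the plain variance.
    """
    from .burden_analysis import compute_burden_profiles

    config = config or SelectionConfig()
    rows = []
    for t in sorted(thresholds):
        cfg_t = SelectionConfig(
            maf_threshold=config.maf_threshold,
            group_fraction_threshold=t,
            protein_changing_classes=config.protein_changing_classes,
        )
        selected = select_genomewide_variants(matrix, annotations, cfg_t)
        if not selected:
            rows.append({"threshold": t, "n_variants": 0, "variability": np.nan})
            continue
        profiles = compute_burden_profiles(matrix, selected, annotations)
        scores = profiles["burden_score"].to_numpy(dtype=float)
        mean = scores.mean()
        if variability == "cv":
            v = scores.std(ddof=1) / mean if mean > 0 else np.nan
        elif variability == "var":
            v = scores.var(ddof=1)
        else:
            raise ValueError(f"unknown variability measure {variability!r}")
        rows.append({"threshold": t, "n_variants": len(selected), "variability": v})

    df = pd.DataFrame(rows)
    valid = df["variability"].dropna()
    df["is_argmin"] = False
    if len(valid):
        df.loc[valid.idxmin(), "is_argmin"] = True
    return df


def argmin_threshold(sweep_table: pd.DataFrame) -> float:
    """Threshold achieving the lowest burden-score variability."""
    hit = sweep_table.loc[sweep_table["is_argmin"], "threshold"]
    if hit.empty:
        raise ValueError("no threshold with defined variability")
    return float(hit.iloc[0])
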