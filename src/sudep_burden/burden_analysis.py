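"""Per-individual deleteriousness burden scores and group comparisons.

Each individual's burden score is the sum of the scaled deleteriousness
scores of every selected variant they carry; "carried" is presence-based
(a heterozygote and a homozygote contribute the variant's score once), and
a missing genotype contributes nothing.  Groups are compared with the
two-tailed Wilcoxon rank-sum test — mid-ranks for ties, tie-corrected
normal approximation without continuity correction, and an automatic
exact-enumeration branch for very small pooled samples — with Bonferroni
control over the six comparisons (two metrics × three group pairs).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GROUPS, GenotypeMatrix, VariantRecord

DEFAULT_PAIRS = (
    ("case", "epilepsy_control"),
    ("case", "disease_control"),
    ("epilepsy_control", "disease_control"),
)
METRICS = ("burden_score", "variant_count")


def compute_burden_profiles(
    matrix: GenotypeMatrix,
    selected: set[str] | list[str],
    annotations: dict[str, VariantRecord],
    dosage: bool = False,
) -> pd.DataFrame:
    """Burden score and carried-variant count per sample.

    ``dosage=True`` weights each variant by allele count (1 or 2) instead
    of carrier presence.
    """
    selected = [k for k in matrix.variants if k in set(selected)]
    missing_ann = [k for k in selected if k not in annotations]
    if missing_ann:
        raise KeyError(f"selected variant(s) without annotation: {missing_ann[:5]}")
    idx = [matrix.variant_index(k) for k in selected]
    geno = matrix.geno[:, idx]
    cadd = np.array([annotations[k].cadd_scaled for k in selected])

    carried = (geno == 1) | (geno == 2)
    weights = np.where(geno > 0, geno, 0) if dosage else carried.astype(int)
    scores = weights @ cadd if len(selected) else np.zeros(matrix.n_samples)
    counts = carried.sum(axis=1) if len(selected) else np.zeros(
        matrix.n_samples, dtype=int
    )
    return pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "group": matrix.groups,
            "burden_score": scores.astype(float),
            "variant_count": counts.astype(int),
        }
    )


def wilcoxon_rank_sum(values_a, values_b, exact_limit: int = 12):
    """Two-tailed Wilcoxon rank-sum test, Stata ``ranksum`` convention.

    Mid-ranks for ties; normal approximation with tie-corrected variance
    and no continuity correction.  When ``n_a + n_b <= exact_limit`` the
    two-sided p is obtained by exhaustive enumeration of rank splits
    (counting splits whose rank-sum deviates from its null mean at least
    as much as observed).

    Returns ``(z, p_two_sided)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups must be non-empty")
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return 0.0, 1.0
    z = (w - mu) / math.sqrt(var)

    if n <= exact_limit:
        dev = abs(w - mu)
        hits = total = 0
        for comb in itertools.combinations(range(n), n_a):
            total += 1
            if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def summarize_groups(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean, median and interquartile range per group and metric."""
    rows = []
    for metric in METRICS:
        for g in GROUPS:
            x = profiles.loc[profiles["group"] == g, metric].to_numpy(float)
            if len(x) == 0:
                raise ValueError(f"group {g!r} is empty")
            q1, q3 = np.percentile(x, [25, 75])
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "n": len(x),
                    "mean": x.mean(),
                    "median": float(np.median(x)),
                    "q1": q1,
                    "q3": q3,
                    "iqr": q3 - q1,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    profiles: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    n_tests: int = 6,
    base_alpha: float = 0.05,
) -> pd.DataFrame:
    """The six Wilcoxon comparisons with Bonferroni-corrected significance."""
    alpha = base_alpha / n_tests
    rows = []
    for metric in METRICS:
        for ga, gb in pairs:
            xa = profiles.loc[profiles["group"] == ga, metric].to_numpy(float)
            xb = profiles.loc[profiles["group"] == gb, metric].to_numpy(float)
            if len(xa) == 0 or len(xb) == 0:
                raise ValueError(f"empty group in comparison {ga} vs {gb}")
            z, p = wilcoxon_rank_sum(xa, xb)
            rows.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "z_statistic": z,
                    "p_two_sided": p,
                    "bonferroni_alpha": alpha,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def exclude_gene_and_recompute(
    matrix: GenotypeMatrix,
    selected: set[str],
    gene: str,
    annotations: dict[str, VariantRecord],
    dosage: bool = False,
) -> tuple[pd.DataFrame, set[str]]:
    """Post hoc single-gene exclusion: drop the gene's variants from the
    selection and recompute all burden profiles.

    Returns ``(profiles, reduced_selection)``.  An absent gene is a no-op
    with a warning.
    """
    gene_keys = {k for k in selected if annotations[k].gene == gene}
    if not gene_keys:
        known = {annotations[k].gene for k in annotations}
        if gene not in known:
            warnings.warn(f"gene {gene!r} not present in annotations; no-op",
                          stacklevel=2)
    reduced = set(selected) - gene_keys
    profiles = compute_burden_profiles(matrix, reduced, annotations,
                                       dosage=dosage)
    return profiles, reduced


def plot_burden_violin(profiles: pd.DataFrame, path, metric="burden_score"):
    """Violin plot of a per-individual metric by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [
        profiles.loc[profiles["group"] == g, metric].to_numpy(float)
        for g in GROUPS
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(GROUPS) + 1), GROUPS)
    ax.set_ylabel(metric.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
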