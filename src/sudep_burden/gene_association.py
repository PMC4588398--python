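"""Gene-based unique-variant association testing.

For each gene, variants are refined to rare, protein-changing sites with a
scaled deleteriousness score >= 15 that are absent from the epilepsy
control cohort; the analysis then compares cases against disease controls
only.  Two statistics are computed per gene:

* a one-tailed burden statistic — the cumulative non-reference allele
  count over variants exclusive to cases (more case-exclusive alleles =
  more case burden), and
* the two-tailed C-alpha statistic
  ``T = sum_i [(y_i - n_i p0_i)^2 - n_i p0_i (1 - p0_i)]`` where ``y_i``
  is the variant's allele count in cases, ``n_i`` its count in cases plus
  controls, and ``p0_i`` the fraction of genotyped individuals that are
  cases; T grows when allele sharing departs from binomial expectation in
  either direction, so risk and protective variants both register.

Empirical p-values come from adaptive phenotype-label permutation: labels
are swapped uniformly across the case + disease-control pool, the
exclusivity partition and statistic are recomputed inside every
permutation, and a gene stops early once the observed statistic has been
exceeded ``exceedance_stop`` times (clearly not associated).  The smallest
p-value achievable given a gene's carrier configuration (its I-value)
gates the adjusted Bonferroni correction: only genes with I below the
threshold are counted as tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import MISSING, GenotypeMatrix, VariantRecord
from .variant_selection import SelectionConfig, is_protein_changing, passes_rare_filter

_STAT_TOL = 1e-9


@dataclass
class PermutationPlan:
    b_max: int = 1_000_000
    exceedance_stop: int = 100
    batch: int = 1000
    seed: int = 0
    i_threshold: float = 1e-3
    base_alpha: float = 0.05
    tests_per_gene: int = 2

    def __post_init__(self) -> None:
        if not (self.b_max >= self.batch >= 1):
            raise ValueError("need b_max >= batch >= 1")
        if self.exceedance_stop < 1:
            raise ValueError("exceedance_stop must be >= 1")


@dataclass
class GeneVariantSet:
    """Retained variants of one gene, restricted to the case +
    disease-control individuals used by the permutation test."""

    gene: str
    keys: list[str]
    cadd: np.ndarray            # scaled score per variant
    geno: np.ndarray            # (n_individuals, n_variants) codes, MISSING kept
    case_mask: np.ndarray       # observed labels over the same individuals

    @property
    def n_variants(self) -> int:
        return len(self.keys)

    def allele_counts(self, case_mask: np.ndarray | None = None):
        """(y_case, y_ctrl, n_case_genotyped, n_ctrl_genotyped) per variant."""
        mask = self.case_mask if case_mask is None else case_mask
        pos = np.where(self.geno > 0, self.geno, 0)
        called = self.geno != MISSING
        y_case = pos[mask].sum(axis=0)
        y_ctrl = pos[~mask].sum(axis=0)
        n_case_g = called[mask].sum(axis=0)
        n_ctrl_g = called[~mask].sum(axis=0)
        return y_case, y_ctrl, n_case_g, n_ctrl_g

    def case_exclusive(self) -> np.ndarray:
        y_case, y_ctrl, _, _ = self.allele_counts()
        return (y_case > 0) & (y_ctrl == 0)

    def ctrl_exclusive(self) -> np.ndarray:
        y_case, y_ctrl, _, _ = self.allele_counts()
        return (y_ctrl > 0) & (y_case == 0)

    def carriers(self) -> np.ndarray:
        """Individuals carrying >= 1 retained non-reference allele."""
        return (self.geno > 0).any(axis=1)


def build_gene_sets(
    matrix: GenotypeMatrix,
    annotations: dict[str, VariantRecord],
    selection: SelectionConfig | None = None,
    cadd_min: float = 15.0,
) -> dict[str, GeneVariantSet]:
    """Apply the gene-stage variant refinement and group by gene.

    Filters: protein-changing, rare, scaled score >= ``cadd_min``, zero
    non-reference alleles among epilepsy controls, and at least one copy in
    the case + disease-control pool.  Genes with no surviving variant are
    omitted.
    """
    selection = selection or SelectionConfig()
    epi = matrix.group_mask("epilepsy_control")
    cc = matrix.group_mask("case") | matrix.group_mask("disease_control")
    case_mask_cc = (matrix.groups == "case")[cc]

    pos = np.where(matrix.geno > 0, matrix.geno, 0)
    y_epi = pos[epi].sum(axis=0) if epi.any() else np.zeros(matrix.n_variants)
    y_cc = pos[cc].sum(axis=0)

    keep_idx: dict[str, list[int]] = {}
    for j, key in enumerate(matrix.variants):
        rec = annotations[key]
        if not is_protein_changing(rec, selection):
            continue
        if not passes_rare_filter(rec, selection):
            continue
        if rec.cadd_scaled < cadd_min:
            continue
        if y_epi[j] > 0:  # present in epilepsy controls -> excluded entirely
            continue
        if y_cc[j] < 1:
            continue
        keep_idx.setdefault(rec.gene, []).append(j)

    out: dict[str, GeneVariantSet] = {}
    geno_cc = matrix.geno[cc]
    for gene, idx in keep_idx.items():
        out[gene] = GeneVariantSet(
            gene=gene,
            keys=[matrix.variants[j] for j in idx],
            cadd=np.array([annotations[matrix.variants[j]].cadd_scaled
                           for j in idx]),
            geno=geno_cc[:, idx].copy(),
            case_mask=case_mask_cc.copy(),
        )
    return out


def cumulative_maf_pct(allele_count: int, n_genotyped: float) -> float:
    """Cumulative minor allele frequency as a percent of 2N chromosomes,
    rounded to two decimals (report convention)."""
    if n_genotyped < 1:
        raise ValueError("n_genotyped must be >= 1")
    return round(100.0 * allele_count / (2.0 * n_genotyped), 2)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def burden_statistic(gene_set: GeneVariantSet,
                     case_mask: np.ndarray | None = None) -> int:
    """Cumulative allele count over case-exclusive variants (one-tailed)."""
    y_case, y_ctrl, _, _ = gene_set.allele_counts(case_mask)
    excl = (y_case > 0) & (y_ctrl == 0)
    return int(y_case[excl].sum())


def calpha_statistic(gene_set: GeneVariantSet,
                     case_mask: np.ndarray | None = None) -> float:
    """C-alpha overdispersion statistic T over variants with >= 1 copy."""
    y_case, y_ctrl, n_case_g, n_ctrl_g = gene_set.allele_counts(case_mask)
    n = y_case + y_ctrl
    use = n >= 1
    if not use.any():
        raise ValueError(f"gene {gene_set.gene}: no variants with copies")
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = n_case_g / (n_case_g + n_ctrl_g)
    y, n, p0 = y_case[use], n[use], p0[use]
    return float(np.sum((y - n * p0) ** 2 - n * p0 * (1 - p0)))


def _batch_statistics(gene_set: GeneVariantSet, masks: np.ndarray,
                      which: str) -> np.ndarray:
    """Vectorised statistics for a (B, n_individuals) batch of case masks.

    The exclusivity partition (burden) and the per-variant case fraction
    p0 (C-alpha) are recomputed for every permuted labelling, exactly as
    the observed statistic is constructed.
    """
    pos = np.where(gene_set.geno > 0, gene_set.geno, 0).astype(np.int64)
    m = masks.astype(np.int64)
    y_case = m @ pos                      # (B, V)
    y_tot = pos.sum(axis=0)               # (V,)
    if which == "burden":
        excl = (y_case == y_tot[None, :]) & (y_case > 0)
        return (y_case * excl).sum(axis=1).astype(float)
    if which == "calpha":
        called = (gene_set.geno != MISSING).astype(np.int64)
        n_case_g = m @ called
        n_g = called.sum(axis=0)
        use = y_tot >= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            p0 = n_case_g[:, use] / n_g[None, use]
        y = y_case[:, use]
        n = y_tot[None, use]
        return np.sum((y - n * p0) ** 2 - n * p0 * (1 - p0), axis=1)
    raise ValueError(f"unknown statistic {which!r}")


_OBSERVED = {"burden": burden_statistic, "calpha": calpha_statistic}


def adaptive_permutation(
    statistic: str,
    gene_set: GeneVariantSet,
    plan: PermutationPlan,
    rng: np.random.Generator | None = None,
):
    """Empirical upper-tail p by adaptive label permutation.

    ``p = (k + 1) / (B + 1)`` with ``k`` the number of permuted statistics
    at least as large as the observed one; permutation stops once ``k``
    reaches ``plan.exceedance_stop`` (the gene is clearly not associated)
    or ``plan.b_max`` permutations have been spent.

    Returns ``(p, perms_used, exhausted)`` where ``exhausted`` flags a
    gene that ran to ``b_max`` without reaching the exceedance stop.
    """
    if statistic not in _OBSERVED:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = rng or np.random.default_rng(plan.seed)
    observed = float(_OBSERVED[statistic](gene_set))
    n_ind = len(gene_set.case_mask)
    n_case = int(gene_set.case_mask.sum())

    k = 0
    done = 0
    while done < plan.b_max:
        b = min(plan.batch, plan.b_max - done)
        order = np.argsort(rng.random((b, n_ind)), axis=1)[:, :n_case]
        masks = np.zeros((b, n_ind), dtype=bool)
        np.put_along_axis(masks, order, True, axis=1)
        stats_b = _batch_statistics(gene_set, masks, statistic)
        k += int((stats_b >= observed - _STAT_TOL).sum())
        done += b
        if k >= plan.exceedance_stop:
            break
    p = (k + 1) / (done + 1)
    exhausted = done >= plan.b_max and k < plan.exceedance_stop
    return float(p), done, exhausted


def i_value(gene_set: GeneVariantSet,
            case_mask: np.ndarray | None = None) -> float:
    """Smallest achievable empirical p for the gene's carrier configuration.

    With ``c`` carrier individuals among ``N``, of whom ``n_case`` are
    labelled cases under permutation, the most extreme configuration puts
    ``min(c, n_case)`` carriers among the cases; its probability under
    uniform label permutation is the hypergeometric point mass, which for
    ``c <= n_case`` reduces to ``prod_{j<c} (n_case - j) / (N - j)``.
    No carriers -> 1.
    """
    mask = gene_set.case_mask if case_mask is None else case_mask
    c = int(gene_set.carriers().sum())
    if c == 0:
        return 1.0
    n = len(mask)
    n_case = int(mask.sum())
    x_max = min(c, n_case)
    return float(hypergeom.pmf(x_max, n, c, n_case))


def adjusted_bonferroni(results: pd.DataFrame,
                        plan: PermutationPlan) -> pd.DataFrame:
    """Significance flags correcting only for genes powered to associate.

    ``m = tests_per_gene x #{genes with I < i_threshold}``; the corrected
    level is ``base_alpha / m``.  With no powered genes, no tests are
    declared and every flag is False.
    """
    out = results.copy()
    out["tested"] = out["i_value"] < plan.i_threshold
    m = plan.tests_per_gene * int(out["tested"].sum())
    alpha = plan.base_alpha / m if m > 0 else np.nan
    out["bonferroni_alpha"] = alpha
    for stat in ("burden", "calpha"):
        col = f"p_{stat}"
        if col in out.columns:
            out[f"significant_{stat}"] = (
                out["tested"] & (m > 0) & (out[col] < alpha)
            )
    return out


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_gene_association(
    matrix: GenotypeMatrix,
    annotations: dict[str, VariantRecord],
    plan: PermutationPlan | None = None,
    selection: SelectionConfig | None = None,
    cadd_min: float = 15.0,
    permute_untested: bool = False,
) -> pd.DataFrame:
    """Per-gene association table (counts, cumulative MAF %, statistics,
    empirical p-values, I-value, significance flags).

    Permutation is spent only on genes powered to reach the corrected
    level (``I < i_threshold``) unless ``permute_untested`` is set.
    """
    plan = plan or PermutationPlan()
    gene_sets = build_gene_sets(matrix, annotations, selection, cadd_min)

    rows = []
    rng = np.random.default_rng(plan.seed)
    for gene in sorted(gene_sets):
        gs = gene_sets[gene]
        y_case, y_ctrl, n_case_g, n_ctrl_g = gs.allele_counts()
        iv = i_value(gs)
        row = {
            "gene": gene,
            "n_variants": gs.n_variants,
            "cum_case_alleles": int(y_case.sum()),
            "cum_ctrl_alleles": int(y_ctrl.sum()),
            "cum_maf_case_pct": cumulative_maf_pct(
                int(y_case.sum()), float(n_case_g.mean())
            ),
            "cum_maf_ctrl_pct": cumulative_maf_pct(
                int(y_ctrl.sum()), float(n_ctrl_g.mean())
            ),
            "burden_stat": burden_statistic(gs),
            "calpha_stat": calpha_statistic(gs),
            "i_value": iv,
            "p_burden": np.nan,
            "p_calpha": np.nan,
            "perms_used": 0,
            "perms_exhausted": False,
        }
        if iv < plan.i_threshold or permute_untested:
            p_b, used_b, ex_b = adaptive_permutation("burden", gs, plan, rng)
            p_c, used_c, ex_c = adaptive_permutation("calpha", gs, plan, rng)
            row.update(
                p_burden=p_b,
                p_calpha=p_c,
                perms_used=max(used_b, used_c),
                perms_exhausted=ex_b or ex_c,
            )
        rows.append(row)

    if not rows:
        return pd.DataFrame(
            columns=["gene", "n_variants", "cum_case_alleles",
                     "cum_ctrl_alleles", "i_value", "tested"]
        )
    return adjusted_bonferroni(pd.DataFrame(rows), plan)
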