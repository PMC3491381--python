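"""Differential alternative-polyadenylation statistics.

Per-transcript usage shifts are tested by a Pearson chi-square of
independence on the peaks x conditions count table (significance cutoff
0.001, no continuity correction).  The direction of a significant shift
comes from the coverage-weighted mean cleavage-site ordinal

    <CS_J> = sum_j w_j * j,   w_j = E_j / sum_k E_k,

which decreases under 3'-UTR shortening.  Relative usage of individual
sites is the poly(A) site usage index

    PUI_j = log2(E_j / <E>),  <E> the geometric mean of the E_j,

whose proximal (j=1) median over transcripts is the global shortening
measure.  Direction imbalances are scored with an upper binomial tail at
p=1/2, and gene-set expression shifts with a two-sample rank-sum test.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import InputError, UntestableTableError

logger = logging.getLogger(__name__)

ALPHA = 0.001
PUI_PSEUDOCOUNT = 1.0
EXACT_RANKSUM_MAX_N = 25


# ---------------------------------------------------------------------------
# Result records

@dataclass
class TranscriptAPAResult:
    transcript_id: str
    chi2: float
    df: int
    p: float
    cs_index: dict  # condition -> <CS_J>
    direction: str = "none"  # shortened | lengthened | none


@dataclass
class DirectionTestResult:
    k: int
    n: int
    p_binomial: float
    log10_p: float


@dataclass
class GeneSetShiftResult:
    target_fc: np.ndarray
    background_fc: np.ndarray
    p_wilcoxon: float


@dataclass
class IntronicShiftSummary:
    results: list = field(default_factory=list)  # (transcript_id, chi2, p, toward_intronic)
    n_tested: int = 0
    n_significant: int = 0
    k_toward_intronic: int = 0
    direction_test: DirectionTestResult | None = None


# ---------------------------------------------------------------------------
# Core tests

def chi_square_usage(table, alpha: float = ALPHA) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a peaks x conditions table.

    Returns ``(chi2, df, p)``.  Tables with a zero expected cell (an empty
    row or column margin) are untestable and rejected.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise UntestableTableError(f"need a >=2x>=2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise UntestableTableError("negative counts")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise UntestableTableError(
            "zero row or column margin gives a zero expected cell"
        )
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def weighted_cs_index(levels) -> float:
    """Coverage-weighted mean cleavage-site ordinal <CS_J> over ordinals 1..N."""
    levels = np.asarray(levels, dtype=float)
    if (levels < 0).any():
        raise InputError("peak levels must be non-negative")
    total = levels.sum()
    if total == 0:
        raise InputError("all-zero levels: <CS_J> undefined")
    j = np.arange(1, len(levels) + 1)
    return float((levels / total * j).sum())


def classify_shift(
    cs_index: dict, p: float, from_cond: str, to_cond: str, alpha: float = ALPHA
) -> str:
    """Direction of a usage shift in ``to_cond`` relative to ``from_cond``."""
    if p >= alpha:
        return "none"
    a, b = cs_index[from_cond], cs_index[to_cond]
    if b < a:
        return "shortened"
    if b > a:
        return "lengthened"
    logger.warning("significant shift (p=%.3g) with equal <CS_J>; direction none", p)
    return "none"


def binomial_direction_test(k: int, n: int, p0: float = 0.5) -> DirectionTestResult:
    """Upper tail P(X >= k), X ~ Binomial(n, p0), computed in log space."""
    if n <= 0:
        raise InputError("n must be > 0")
    if not 0 <= k <= n:
        raise InputError(f"k must be in [0, n], got k={k}, n={n}")
    # summed in log space so the tail stays resolved far below 1e-300
    ks = np.arange(k, n + 1)
    logp = float(special.logsumexp(stats.binom.logpmf(ks, n, p0))) if k <= n else -np.inf
    logp = min(logp, 0.0)
    p = float(np.exp(logp))
    return DirectionTestResult(k=k, n=n, p_binomial=p, log10_p=float(logp / math.log(10)))


def compute_pui(levels, pseudocount: float = PUI_PSEUDOCOUNT) -> np.ndarray:
    """Per-site usage index PUI_j = log2(E_j / <E>); sums to 0 over sites."""
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2:
        raise InputError("PUI needs at least two sites")
    e = levels + pseudocount
    if (e <= 0).any():
        raise InputError("levels + pseudocount must be positive")
    log2e = np.log2(e)
    return log2e - log2e.mean()


def proximal_pui_median(pui_by_transcript: dict, condition: str) -> float:
    """Median proximal (j=1) PUI across multi-site transcripts for one condition.

    ``pui_by_transcript`` maps transcript -> {condition -> PUI vector}.
    """
    values = [
        conds[condition][0]
        for conds in pui_by_transcript.values()
        if condition in conds
    ]
    if not values:
        raise InputError(f"no multi-site transcripts with PUI for {condition!r}")
    return float(np.median(values))


# ---------------------------------------------------------------------------
# Transcript-level analysis over usage tables

@dataclass
class UsageTable:
    """Ordered 3'-UTR peak levels (rows, ordinal j) x conditions (columns)."""

    transcript_id: str
    conditions: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)


def analyze_usage_tables(
    tables: list,
    from_cond: str,
    to_cond: str,
    alpha: float = ALPHA,
) -> tuple[list, list]:
    """Chi-square + direction for every testable table.

    Returns ``(results, untestable_ids)``; untestable tables (zero margin)
    are skipped with a log entry.
    """
    results, untestable = [], []
    for t in tables:
        try:
            chi2, df, p = chi_square_usage(t.counts, alpha=alpha)
        except UntestableTableError as exc:
            logger.info("%s untestable: %s", t.transcript_id, exc)
            untestable.append(t.transcript_id)
            continue
        cs_index = {}
        for ci, cond in enumerate(t.conditions):
            col = t.counts[:, ci]
            cs_index[cond] = weighted_cs_index(col) if col.sum() > 0 else float("nan")
        direction = classify_shift(cs_index, p, from_cond, to_cond, alpha=alpha)
        results.append(
            TranscriptAPAResult(
                transcript_id=t.transcript_id,
                chi2=chi2, df=df, p=p,
                cs_index=cs_index, direction=direction,
            )
        )
    return results, untestable


def direction_tally(results, direction: str = "shortened") -> DirectionTestResult:
    """Binomial tail on the share of significant transcripts shifting one way."""
    significant = [r for r in results if r.direction != "none"]
    k = sum(1 for r in significant if r.direction == direction)
    n = len(significant)
    if n == 0:
        return DirectionTestResult(k=0, n=0, p_binomial=float("nan"), log10_p=float("nan"))
    return binomial_direction_test(k, n)


def pui_tables(usage_tables, pseudocount: float = PUI_PSEUDOCOUNT) -> dict:
    """Per-transcript, per-condition PUI vectors from usage tables."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for t in usage_tables:
        if t.counts.shape[0] < 2:
            continue
        out[t.transcript_id] = {
            cond: compute_pui(t.counts[:, ci], pseudocount=pseudocount)
            for ci, cond in enumerate(t.conditions)
        }
    return out


# ---------------------------------------------------------------------------
# Intronic-vs-3'UTR usage shifts

def intronic_shift_test(
    region_tables: list,
    to_idx: int = 0,
    from_idx: int = 1,
    alpha: float = ALPHA,
) -> IntronicShiftSummary:
    """Test intronic vs 3'-UTR cleavage usage per transcript across conditions.

    ``region_tables`` holds ``(transcript_id, intronic_counts, utr3_counts)``
    with one count per condition.  A transcript counts as shifting toward
    intronic usage when significant and its intronic share is higher in
    condition ``to_idx`` (the proliferative one); the tally gets a binomial
    tail.
    """
    summary = IntronicShiftSummary()
    for tid, intronic, utr3 in region_tables:
        intronic = np.asarray(intronic, dtype=float)
        utr3 = np.asarray(utr3, dtype=float)
        table = np.vstack([intronic, utr3])
        try:
            chi2, df, p = chi_square_usage(table, alpha=alpha)
        except UntestableTableError as exc:
            logger.info("%s intronic test skipped: %s", tid, exc)
            continue
        summary.n_tested += 1
        toward = False
        if p < alpha:
            summary.n_significant += 1
            share_to = intronic[to_idx] / (intronic[to_idx] + utr3[to_idx])
            share_from = intronic[from_idx] / (intronic[from_idx] + utr3[from_idx])
            toward = share_to > share_from
            if toward:
                summary.k_toward_intronic += 1
        summary.results.append((tid, chi2, p, toward))
    if summary.n_significant > 0:
        summary.direction_test = binomial_direction_test(
            summary.k_toward_intronic, summary.n_significant
        )
    return summary


# ---------------------------------------------------------------------------
# Cross-system core set

def core_set_intersection(results_a, results_b):
    """Transcripts significant in both systems, split by direction agreement.

    Returns ``(consistent_ids, opposing_ids, enrichment_p)``; the
    enrichment p is the upper binomial tail of the consistent-shortened
    count against the larger single-system shortened fraction.
    """
    sig_a = {r.transcript_id: r.direction for r in results_a if r.direction != "none"}
    sig_b = {r.transcript_id: r.direction for r in results_b if r.direction != "none"}
    shared = sorted(set(sig_a) & set(sig_b))
    consistent = [t for t in shared if sig_a[t] == sig_b[t]]
    opposing = [t for t in shared if sig_a[t] != sig_b[t]]
    if not consistent:
        return consistent, opposing, None
    frac_a = sum(1 for d in sig_a.values() if d == "shortened") / len(sig_a)
    frac_b = sum(1 for d in sig_b.values() if d == "shortened") / len(sig_b)
    p0 = max(frac_a, frac_b)
    k = sum(1 for t in consistent if sig_a[t] == "shortened")
    p = binomial_direction_test(k, len(consistent), p0=p0).p_binomial
    return consistent, opposing, p


# ---------------------------------------------------------------------------
# Expression-level indices and gene-set shifts

def proliferation_index(expr, cell_cycle_genes, condition: str) -> float:
    """log2 of median cell-cycle-gene expression over median overall expression."""
    if condition not in expr.columns:
        raise InputError(f"condition {condition!r} not in expression matrix")
    cc = [g for g in expr.index if g in set(cell_cycle_genes)]
    if not cc:
        raise InputError("no cell-cycle genes present in the expression matrix")
    col = expr[condition]
    return float(np.log2(col.loc[cc].median() / col.median()))


def rank_sum_test(x, y) -> float:
    """Two-sided two-sample rank-sum p: exact by enumeration when the pooled
    sample is small and tie-free, else normal approximation with continuity
    correction (degenerate all-equal input gives p=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = pooled.size
    tie_free = np.unique(pooled).size == n
    method = "exact" if (n <= EXACT_RANKSUM_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def geneset_shift_test(fold_changes, target_ids) -> GeneSetShiftResult:
    """Rank-sum comparison of per-gene log2 fold-changes: target set versus
    all other genes.  ``fold_changes`` is a mapping or Series gene -> log2 FC."""
    import pandas as pd

    fc = pd.Series(fold_changes, dtype=float)
    target_ids = set(target_ids)
    target = fc.loc[[g for g in fc.index if g in target_ids]]
    background = fc.loc[[g for g in fc.index if g not in target_ids]]
    if target.empty or background.empty:
        raise InputError("target and background sets must both be non-empty")
    p = rank_sum_test(target.to_numpy(), background.to_numpy())
    return GeneSetShiftResult(
        target_fc=target.to_numpy(), background_fc=background.to_numpy(), p_wilcoxon=p
    )


def log2_fold_change(expr, cond_num: str, cond_den: str):
    """Per-gene log2(cond_num / cond_den) on a floored expression matrix."""
    if cond_num not in expr.columns or cond_den not in expr.columns:
        raise InputError("conditions missing from expression matrix")
    return np.log2(expr[cond_num] / expr[cond_den])
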