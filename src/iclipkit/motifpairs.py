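"""Positional trimer enrichment and multivalent pair-motif statistics.

The target trimers are AGA, AAG and GAA. A pair motif is an occurrence of
one target trimer followed by another whose start is at least ``k_min`` (= 3)
positions downstream, so overlapping arrangements such as ``AAGA`` never
qualify. Pair over-representation in a target exon region versus a control
region is tested per exon (presence/absence of >= 1 qualifying pair) with a
one-sided Fisher's exact test, and an empirical false-discovery rate is
estimated by re-running the test on exon samples bootstrapped from a
population set.

The degenerate ("Any") pairs fix the upstream trimer and accept any of the
three target trimers downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exonsets import ExonRecord

logger = logging.getLogger(__name__)

TRIMERS = ("AGA", "AAG", "GAA")
DEFAULT_K_MIN = 3
REGIONS = ("exon_first50", "exon_last50",
           "upstream_intron_last50", "downstream_intron_first50")
DEFAULT_REGION_LEN = 50
SIGNIFICANCE_P = 0.0005  # p-values above this are reported not significant


def region_sequence(exon: ExonRecord, region: str,
                    length: int = DEFAULT_REGION_LEN) -> str | None:
    """Extract a region substring, or None when the source is too short."""
    if region == "exon_first50":
        src, piece = exon.sequence, "first"
    elif region == "exon_last50":
        src, piece = exon.sequence, "last"
    elif region == "upstream_intron_last50":
        src, piece = exon.upstream_intron_seq, "last"
    elif region == "downstream_intron_first50":
        src, piece = exon.downstream_intron_seq, "first"
    else:
        raise ValueError(f"unknown region {region!r}")
    if len(src) < length:
        return None
    return src[:length] if piece == "first" else src[-length:]


# ---------------------------------------------------------------------------
# Positional marking
# ---------------------------------------------------------------------------

def mark_positions(
    exons: list[ExonRecord],
    trimers: tuple[str, ...] = TRIMERS,
    region: str = "exon_last50",
    region_len: int = DEFAULT_REGION_LEN,
) -> tuple[np.ndarray, int]:
    """Per-position counts of exons with a target trimer starting there.

    Returns (counts vector of length region_len - 2, number of exons used).
    Exons whose region sequence is shorter than ``region_len`` are skipped.
    """
    counts = np.zeros(region_len - 2, dtype=np.int64)
    used = 0
    for ex in exons:
        seq = region_sequence(ex, region, region_len)
        if seq is None:
            continue
        used += 1
        for i in range(region_len - 2):
            if seq[i:i + 3] in trimers:
                counts[i] += 1
    return counts, used


@dataclass
class PositionalCounts:
    region: str
    target_counts: np.ndarray
    control_counts: np.ndarray
    n_target: int
    n_control: int
    p_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region": self.region,
            "position": np.arange(len(self.target_counts)),
            "target_marked": self.target_counts,
            "control_marked": self.control_counts,
            "p_fisher": self.p_values,
        })


def positional_tests(
    target_exons: list[ExonRecord],
    control_exons: list[ExonRecord],
    trimers: tuple[str, ...] = TRIMERS,
    region: str = "exon_last50",
    region_len: int = DEFAULT_REGION_LEN,
    alternative: str = "two-sided",
) -> PositionalCounts:
    """Fisher's exact test of per-position mark counts, target vs control."""
    t_counts, n_t = mark_positions(target_exons, trimers, region, region_len)
    c_counts, n_c = mark_positions(control_exons, trimers, region, region_len)
    pvals = np.ones(len(t_counts))
    for i, (a, c) in enumerate(zip(t_counts, c_counts)):
        table = [[int(a), n_t - int(a)], [int(c), n_c - int(c)]]
        pvals[i] = stats.fisher_exact(table, alternative=alternative).pvalue
    return PositionalCounts(region, t_counts, c_counts, n_t, n_c, pvals)


# ---------------------------------------------------------------------------
# Pair finding
# ---------------------------------------------------------------------------

def find_pairs(
    sequence: str,
    trimers: tuple[str, ...] = TRIMERS,
    k_min: int = DEFAULT_K_MIN,
    max_gap: int | None = None,
) -> list[tuple[int, str, int, str]]:
    """All ordered trimer pairs (up_pos, up_trimer, down_pos, down_trimer).

    Both trimers must lie fully inside ``sequence`` and satisfy
    ``down_pos - up_pos >= k_min`` (start-offset spacing, which excludes
    overlapping arrangements such as AAGA for k_min = 3). ``max_gap``
    optionally caps the start-offset spacing.
    """
    if k_min < 3:
        raise ValueError("k_min must be >= 3 to exclude overlapping trimers")
    occ = [(i, sequence[i:i + 3]) for i in range(len(sequence) - 2)
           if sequence[i:i + 3] in trimers]
    pairs = []
    for ui, (up_pos, up_tri) in enumerate(occ):
        for down_pos, down_tri in occ[ui:]:
            gap = down_pos - up_pos
            if gap < k_min:
                continue
            if max_gap is not None and gap > max_gap:
                break
            pairs.append((up_pos, up_tri, down_pos, down_tri))
    return pairs


def has_pair(
    sequence: str,
    up_trimer: str,
    down_trimer: str | None,
    k_min: int = DEFAULT_K_MIN,
    max_gap: int | None = None,
) -> bool:
    """True iff the sequence contains >= 1 qualifying (up, down) pair.

    ``down_trimer=None`` (or "Any") accepts any target trimer downstream.
    """
    if down_trimer == "Any":
        down_trimer = None
    for _, u, _, d in find_pairs(sequence, TRIMERS, k_min, max_gap):
        if u == up_trimer and (down_trimer is None or d == down_trimer):
            return True
    return False


# ---------------------------------------------------------------------------
# Fisher's exact test (one-sided over-representation)
# ---------------------------------------------------------------------------

def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table [[a, b], [c, d]] under the hypergeometric
    null (one-sided over-representation in the first row)."""
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))


@dataclass
class MotifPairResult:
    up_trimer: str
    down_trimer: str           # specific trimer or "Any"
    region: str
    a: int                     # target exons with pair
    b: int                     # target exons without pair
    c: int                     # control exons with pair
    d: int                     # control exons without pair
    p_fisher: float
    fdr_bootstrap: float | None = None
    fdr_upper_bound: bool = False  # True when fdr reported as < 1/n_trials
    rank: int | None = None

    @property
    def pair_name(self) -> str:
        return f"{self.up_trimer}->{self.down_trimer}"

    @property
    def significant(self) -> bool:
        return self.p_fisher <= SIGNIFICANCE_P


def all_pair_specs() -> list[tuple[str, str]]:
    """The 9 specific ordered pairs plus the 3 Any-downstream degenerate ones."""
    specs = [(u, d) for u in TRIMERS for d in TRIMERS]
    specs += [(u, "Any") for u in TRIMERS]
    return specs


def pair_presence_matrix(
    exons: list[ExonRecord],
    region: str,
    k_min: int,
    region_len: int = DEFAULT_REGION_LEN,
    max_gap: int | None = None,
) -> np.ndarray:
    """(n_exons, 12) boolean pair-presence matrix in all_pair_specs order.

    Exons whose region sequence is unavailable count as all-False rows
    (they are still part of the set denominator only if included upstream;
    callers should pre-filter if needed).
    """
    specs = all_pair_specs()
    mat = np.zeros((len(exons), len(specs)), dtype=bool)
    for i, ex in enumerate(exons):
        seq = region_sequence(ex, region, region_len)
        if seq is None:
            continue
        found = {(u, d) for _, u, _, d in find_pairs(seq, TRIMERS, k_min, max_gap)}
        if not found:
            continue
        ups = {u for u, _ in found}
        for j, (u, d) in enumerate(specs):
            if d == "Any":
                mat[i, j] = u in ups
            else:
                mat[i, j] = (u, d) in found
    return mat


def pair_test(
    target_exons: list[ExonRecord],
    control_exons: list[ExonRecord],
    up_trimer: str,
    down_trimer: str,
    region: str = "exon_last50",
    k_min: int = DEFAULT_K_MIN,
    max_gap: int | None = None,
) -> MotifPairResult:
    """One pair-motif over-representation test (target vs control exons)."""
    if not target_exons or not control_exons:
        raise ValueError("target and control exon sets must be non-empty")
    a = sum(has_pair(region_sequence(ex, region) or "", up_trimer,
                     down_trimer, k_min, max_gap) for ex in target_exons)
    c = sum(has_pair(region_sequence(ex, region) or "", up_trimer,
                     down_trimer, k_min, max_gap) for ex in control_exons)
    b, d = len(target_exons) - a, len(control_exons) - c
    return MotifPairResult(up_trimer, down_trimer, region, a, b, c, d,
                           fisher_one_sided(a, b, c, d))


def rank_all_pairs(
    target_exons: list[ExonRecord],
    control_exons: list[ExonRecord],
    region: str = "exon_last50",
    k_min: int = DEFAULT_K_MIN,
    max_gap: int | None = None,
) -> list[MotifPairResult]:
    """Run all 12 pair tests and rank them.

    Ranking: smallest p, then larger target count a, then pair name.
    """
    results = [pair_test(target_exons, control_exons, u, d, region, k_min,
                         max_gap) for u, d in all_pair_specs()]
    results.sort(key=lambda r: (r.p_fisher, -r.a, r.pair_name))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


# ---------------------------------------------------------------------------
# Bootstrap FDR
# ---------------------------------------------------------------------------

def bootstrap_fdr(
    observed_results: list[MotifPairResult],
    population_exons: list[ExonRecord],
    control_exons: list[ExonRecord],
    n_trials: int = 10000,
    sample_size: int = 109,
    k_min: int = DEFAULT_K_MIN,
    rng: np.random.Generator | int = 0,
    max_gap: int | None = None,
    population_presence: np.ndarray | None = None,
    family: str = "min_p",
) -> list[MotifPairResult]:
    """Empirical FDR for each observed pair result.

    Each trial draws ``sample_size`` exons without replacement from the
    population and recomputes every pair test against the same control set.
    With ``family="min_p"`` (default) the FDR of a pair is the fraction of
    trials in which *any* tested pair reaches a p-value <= the observed one —
    a min-P bootstrap that absorbs the best-of-family selection, so the FDR
    of the top-ranked pair is calibrated under the null. ``family="per_pair"``
    instead compares each pair only against its own trial p distribution.
    A pair beaten by zero trials is reported with
    ``fdr_bootstrap = 1 / n_trials`` and ``fdr_upper_bound = True``.
    """
    if family not in ("min_p", "per_pair"):
        raise ValueError("family must be 'min_p' or 'per_pair'")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(population_exons) < sample_size:
        raise ValueError("population smaller than sample_size")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    region = observed_results[0].region
    specs = all_pair_specs()
    by_spec = {(r.up_trimer, r.down_trimer): r for r in observed_results}

    pop = (population_presence if population_presence is not None else
           pair_presence_matrix(population_exons, region, k_min, max_gap=max_gap))
    ctrl = pair_presence_matrix(control_exons, region, k_min, max_gap=max_gap)
    n_ctrl = len(control_exons)
    c_counts = ctrl.sum(axis=0)

    # memoize p as a function of the trial count a: the other margins are
    # fixed (row total = sample_size, control column fixed per spec)
    p_by_a = np.empty((len(specs), sample_size + 1))
    a_grid = np.arange(sample_size + 1)
    for j in range(len(specs)):
        c = int(c_counts[j])
        p_by_a[j] = stats.hypergeom.sf(
            a_grid - 1, sample_size + n_ctrl, sample_size, a_grid + c)

    beat = np.zeros(len(specs), dtype=np.int64)
    obs_p = np.array([by_spec[s].p_fisher for s in specs])
    n_pop = len(population_exons)
    cols = np.arange(len(specs))
    for _ in range(n_trials):
        idx = rng.choice(n_pop, size=sample_size, replace=False)
        a_trial = pop[idx].sum(axis=0)
        p_trial = p_by_a[cols, a_trial]
        if family == "min_p":
            beat += p_trial.min() <= obs_p
        else:
            beat += p_trial <= obs_p

    for j, spec in enumerate(specs):
        r = by_spec[spec]
        if beat[j] == 0:
            r.fdr_bootstrap = 1.0 / n_trials
            r.fdr_upper_bound = True
        else:
            r.fdr_bootstrap = beat[j] / n_trials
            r.fdr_upper_bound = False
    return observed_results


# ---------------------------------------------------------------------------
# Trimer-ablating mutation design
# ---------------------------------------------------------------------------

def mutate_trimers(sequence: str) -> tuple[str, list[tuple[int, str, str]]]:
    """Replace every G inside any AGA/AAG/GAA occurrence with C, iterating
    to a fixed point so the output contains no target trimer.

    Returns (mutated sequence, list of (position, from, to) edits).
    """
    seq = list(sequence)
    edits: list[tuple[int, str, str]] = []
    while True:
        targets = set()
        s = "".join(seq)
        for i in range(len(s) - 2):
            if s[i:i + 3] in TRIMERS:
                for k in range(3):
                    if s[i + k] == "G":
                        targets.add(i + k)
        if not targets:
            break
        for pos in sorted(targets):
            edits.append((pos, "G", "C"))
            seq[pos] = "C"
    return "".join(seq), edits


def results_to_frame(results: list[MotifPairResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair": r.pair_name, "region": r.region, "a": r.a, "b": r.b,
        "c": r.c, "d": r.d, "p_fisher": r.p_fisher,
        "fdr_bootstrap": r.fdr_bootstrap, "fdr_upper_bound": r.fdr_upper_bound,
        "rank": r.rank, "significant": r.significant,
    } for r in results])
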