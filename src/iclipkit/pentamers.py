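"""Pentamer Z-score enrichment around crosslink sites.

Observed pentamer statistics in the 61-nt window centred on each crosslink
site are compared with the same statistics computed on randomized site sets,
where every site is re-drawn uniformly within its own annotated region
instance (the region of the same class, in the same gene, that contains it).
Sites outside annotated transcripts are excluded from both tallies.

The default occurrence statistic is windows-containing (a window counts a
pentamer at most once); ``count_mode="occurrences"`` counts every occurrence.
"""

from __future__ import annotations

import itertools
import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import Annotation, PRECEDENCE
from .io import revcomp
from .reads import CrosslinkSite

logger = logging.getLogger(__name__)

BASES = "ACGT"
N_PENTAMERS = 4 ** 5
ALL_PENTAMERS = ["".join(p) for p in itertools.product(BASES, repeat=5)]
SD_FLOOR = 1e-9

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def window_sequences(
    sites: list[CrosslinkSite],
    genome: dict[str, str],
    half_window: int = 30,
    boundary: str = "drop",
) -> tuple[list[str], list[CrosslinkSite]]:
    """Oriented (2*half_window + 1)-nt sequences centred on each site.

    Minus-strand windows are reverse-complemented so position +1 is always
    immediately downstream of the crosslink in transcript orientation. Sites
    closer than ``half_window`` to a contig end are dropped (default) or
    clipped per ``boundary``. Returns (sequences, retained sites).
    """
    if boundary not in ("drop", "clip"):
        raise ValueError("boundary must be 'drop' or 'clip'")
    seqs, kept = [], []
    for s in sites:
        chrom_seq = genome.get(s.chrom)
        if chrom_seq is None:
            continue
        lo, hi = s.position - half_window, s.position + half_window + 1
        if lo < 0 or hi > len(chrom_seq):
            if boundary == "drop":
                continue
            lo, hi = max(0, lo), min(len(chrom_seq), hi)
        w = chrom_seq[lo:hi]
        if s.strand == "-":
            w = revcomp(w)
        seqs.append(w)
        kept.append(s)
    return seqs, kept


# ---------------------------------------------------------------------------
# Site randomization within region instances
# ---------------------------------------------------------------------------

class _RegionLocator:
    """Interval stabbing over raw (non-merged) annotated regions."""

    def __init__(self, annotation: Annotation):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[int],
                                                  list[int], list[str]]] = {}
        tmp: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for g in annotation.genes:
            for r in g.regions:
                tmp.setdefault((g.chrom, g.strand), []).append(
                    (r.start, r.end, r.region_class))
        for key, rows in tmp.items():
            rows.sort()
            starts = [s for s, _, _ in rows]
            ends = [e for _, e, _ in rows]
            cummax = list(itertools.accumulate(ends, max))
            classes = [c for _, _, c in rows]
            self._by_key[key] = (starts, ends, cummax, classes)

    def locate(self, site: CrosslinkSite) -> tuple[int, int, str] | None:
        """Highest-precedence region instance containing the site, or None."""
        entry = self._by_key.get((site.chrom, site.strand))
        if entry is None:
            return None
        starts, ends, cummax, classes = entry
        i = bisect_right(starts, site.position) - 1
        hits = []
        while i >= 0 and cummax[i] > site.position:
            if starts[i] <= site.position < ends[i]:
                hits.append((starts[i], ends[i], classes[i]))
            i -= 1
        if not hits:
            return None
        rank = {c: k for k, c in enumerate(PRECEDENCE)}
        return min(hits, key=lambda h: rank.get(h[2], len(rank)))


def randomize_sites(
    sites: list[CrosslinkSite],
    annotation: Annotation,
    n_rand: int,
    rng: np.random.Generator,
) -> tuple[list[CrosslinkSite], list[list[CrosslinkSite]], int]:
    """Draw ``n_rand`` randomized copies of each annotated site.

    Each copy is uniform over the positions of the region instance containing
    the original site. Unannotated (intergenic) sites are excluded from both
    the retained observed set and the randomized sets; their count is
    returned as the third element.
    """
    locator = _RegionLocator(annotation)
    kept: list[CrosslinkSite] = []
    rand_sets: list[list[CrosslinkSite]] = [[] for _ in range(n_rand)]
    excluded = 0
    for s in sites:
        hit = locator.locate(s)
        if hit is None:
            excluded += 1
            continue
        start, end, _cls = hit
        kept.append(s)
        draws = rng.integers(start, end, size=n_rand)
        for k in range(n_rand):
            rand_sets[k].append(
                CrosslinkSite(s.chrom, s.strand, int(draws[k]), s.cdna_count))
    if excluded:
        logger.info("randomize_sites: %d unannotated sites excluded", excluded)
    return kept, rand_sets, excluded


# ---------------------------------------------------------------------------
# Pentamer counting
# ---------------------------------------------------------------------------

def _encode(seqs: list[str]) -> np.ndarray:
    """(n, L) base-code matrix; sequences must share one length."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all window sequences must have equal length")
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(len(seqs), L)


def _pentamer_codes(mat: np.ndarray) -> np.ndarray:
    """(n, L-4) pentamer codes; windows touching non-ACGT get code 1024."""
    c = mat.astype(np.int32)
    code = (((c[:, :-4] * 4 + c[:, 1:-3]) * 4 + c[:, 2:-2]) * 4
            + c[:, 3:-1]) * 4 + c[:, 4:]
    invalid = np.zeros(code.shape, dtype=bool)
    for k in range(5):
        sl = mat[:, k:mat.shape[1] - 4 + k]
        invalid |= sl == 255
    code[invalid] = N_PENTAMERS
    return code


def pentamer_counts(
    seqs: list[str],
    count_mode: str = "windows",
    weights: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Length-1024 count vector of pentamers over a set of equal-length windows.

    ``windows``: number of windows containing >= 1 occurrence (presence).
    ``occurrences``: total occurrence count.

    ``weights`` (one per window) counts a window that many times — used to
    weight each crosslink-site window by its unique-cDNA count, so a site
    supported by k cDNAs contributes k observations.
    """
    if count_mode not in ("windows", "occurrences"):
        raise ValueError("count_mode must be 'windows' or 'occurrences'")
    codes = _pentamer_codes(_encode(seqs))
    if codes.size == 0:
        return np.zeros(N_PENTAMERS, dtype=np.float64)
    w = (np.ones(codes.shape[0]) if weights is None
         else np.asarray(weights, dtype=np.float64))
    if w.shape[0] != codes.shape[0]:
        raise ValueError("weights must match the number of windows")
    counts = np.zeros(N_PENTAMERS, dtype=np.float64)
    if count_mode == "occurrences":
        flat = codes.ravel()
        wflat = np.repeat(w, codes.shape[1])
        valid = flat < N_PENTAMERS
        np.add.at(counts, flat[valid], wflat[valid])
        return counts
    rows = np.arange(codes.shape[0], dtype=np.int64)[:, None]
    ids = np.unique((rows * (N_PENTAMERS + 1) + codes).ravel())
    pent = ids % (N_PENTAMERS + 1)
    row_of = ids // (N_PENTAMERS + 1)
    valid = pent < N_PENTAMERS
    np.add.at(counts, pent[valid], w[row_of[valid]])
    return counts


def pentamer_z(
    observed_seqs: list[str],
    randomized_seq_sets: list[list[str]],
    count_mode: str = "windows",
    sd_floor: float = SD_FLOOR,
    observed_weights: np.ndarray | list[float] | None = None,
    randomized_weights: list[np.ndarray | list[float]] | None = None,
) -> pd.DataFrame:
    """Per-pentamer Z-score table.

    Columns: ``pentamer, observed, random_mean, random_sd, z,
    never_in_random``. The sd is floored at ``sd_floor`` so pentamers never
    seen in any randomization yield huge-but-finite z, flagged. Optional
    per-window weights (unique-cDNA counts) apply to observed and randomized
    sets alike.
    """
    if not randomized_seq_sets:
        raise ValueError("at least one randomized set is required")
    if not observed_seqs:
        raise ValueError("no observed windows; z-scores undefined")
    obs = pentamer_counts(observed_seqs, count_mode, observed_weights)
    rand = np.stack([
        pentamer_counts(s, count_mode,
                        None if randomized_weights is None
                        else randomized_weights[k])
        for k, s in enumerate(randomized_seq_sets)])
    mean = rand.mean(axis=0)
    sd = rand.std(axis=0, ddof=1) if rand.shape[0] > 1 else np.zeros(N_PENTAMERS)
    z = (obs - mean) / np.maximum(sd, sd_floor)
    return pd.DataFrame({
        "pentamer": ALL_PENTAMERS,
        "observed": obs,
        "random_mean": mean,
        "random_sd": sd,
        "z": z,
        "never_in_random": rand.max(axis=0) == 0,
    })


# ---------------------------------------------------------------------------
# Positional profiles
# ---------------------------------------------------------------------------

def positional_profile(
    top_pentamers: list[str],
    observed_seqs: list[str],
    randomized_seq_sets: list[list[str]],
    half_window: int = 30,
) -> pd.DataFrame:
    """Observed/randomized occurrence-ratio curves per pentamer start offset.

    Offsets run from -half_window to +half_window - 4 (pentamer start
    positions within the window). Ratio conventions: 0/0 -> 1; x/0 -> inf,
    flagged in the ``undefined`` column.
    """
    if not top_pentamers:
        raise ValueError("top_pentamers must be non-empty")
    obs_codes = _pentamer_codes(_encode(observed_seqs))
    rand_codes = [_pentamer_codes(_encode(s)) for s in randomized_seq_sets]
    n_obs = max(len(observed_seqs), 1)
    rows = []
    for pent in top_pentamers:
        code = 0
        for ch in pent:
            code = code * 4 + BASES.index(ch)
        obs_freq = (obs_codes == code).sum(axis=0) / n_obs
        rand_freq = np.mean(
            [(rc == code).sum(axis=0) / max(rc.shape[0], 1)
             for rc in rand_codes], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = obs_freq / rand_freq
        undefined = rand_freq == 0
        ratio = np.where(undefined & (obs_freq == 0), 1.0, ratio)
        ratio = np.where(undefined & (obs_freq > 0), np.inf, ratio)
        for k in range(obs_codes.shape[1]):
            rows.append((pent, k - half_window, obs_freq[k], rand_freq[k],
                         ratio[k], bool(undefined[k] and obs_freq[k] > 0)))
    return pd.DataFrame(rows, columns=["pentamer", "offset", "observed_freq",
                                       "random_freq", "ratio", "undefined"])


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    replicate_a: str
    replicate_b: str
    pearson_r: float
    top_shared: tuple[str, ...]


def concordance(
    score_tables: dict[str, pd.DataFrame],
    top_k: int = 10,
) -> list[ConcordanceResult]:
    """Pearson r over the 1024-dim z vectors for every replicate pair.

    ``top_shared`` lists pentamers ranked in the top-k by z in both
    replicates of a pair. Constant z vectors raise ``ValueError``.
    """
    names = sorted(score_tables)
    if len(names) < 2:
        raise ValueError("need at least two replicates")
    out = []
    for a, b in itertools.combinations(names, 2):
        za = score_tables[a].sort_values("pentamer")["z"].to_numpy()
        zb = score_tables[b].sort_values("pentamer")["z"].to_numpy()
        if np.ptp(za) == 0 or np.ptp(zb) == 0:
            raise ValueError(f"constant z-vector in replicate pair ({a}, {b})")
        r = float(stats.pearsonr(za, zb).statistic)
        top_a = set(score_tables[a].nlargest(top_k, "z")["pentamer"])
        top_b = set(score_tables[b].nlargest(top_k, "z")["pentamer"])
        out.append(ConcordanceResult(a, b, r, tuple(sorted(top_a & top_b))))
    return out


def score_sites(
    sites: list[CrosslinkSite],
    genome: dict[str, str],
    annotation: Annotation,
    n_rand: int = 100,
    half_window: int = 30,
    count_mode: str = "windows",
    seed: int | np.random.Generator = 0,
    weight_by_count: bool = True,
) -> pd.DataFrame:
    """Convenience pipeline: randomize, window, and z-score a site set.

    With ``weight_by_count`` (default) each window counts once per unique
    cDNA at its site, so PCR-deduplicated multi-cDNA sites keep their
    evidential weight.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    kept, rand_sets, _ = randomize_sites(sites, annotation, n_rand, rng)
    obs_seqs, obs_kept = window_sequences(kept, genome, half_window)
    rand_seqs, rand_weights = [], []
    for rs in rand_sets:
        seqs, rs_kept = window_sequences(rs, genome, half_window)
        rand_seqs.append(seqs)
        rand_weights.append([s.cdna_count for s in rs_kept])
    if not weight_by_count:
        return pentamer_z(obs_seqs, rand_seqs, count_mode)
    return pentamer_z(obs_seqs, rand_seqs, count_mode,
                      observed_weights=[s.cdna_count for s in obs_kept],
                      randomized_weights=rand_weights)
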