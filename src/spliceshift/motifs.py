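"""RBP motif enrichment with an exact PWM threshold and a resampling null.

The scan is FIMO-style: each PWM gets a log-odds score threshold calibrated
so that a random background word reaches it with probability <= 0.001.
The score null distribution is computed exactly by dynamic programming over
per-position scores discretized to 0.01-bit bins (rounded down, so the
threshold is conservative).  Hits are counted on the sense strand only:
these are RNA-binding motifs on transcribed sequence.

Enrichment compares the hit count in the regulated event regions against
100 control sets resampled from equivalent regions (same event type, same
region label) of non-regulated events; the z-score normalizes the observed
count by the control mean and standard deviation and calls enrichment at
z > 1.96.  It is computed separately per motif, event type, region
(upstream flank / spliced region / downstream flank) and direction of the
splicing change (dPSI > 0.05 up, dPSI < -0.05 down).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .datamodel import (GenomicInterval, MotifModel, SplicingEvent,
                        encode_sequence, reverse_complement, to_rna)

logger = logging.getLogger(__name__)

REGION_LABELS = ("upstream_flank", "spliced_region", "downstream_flank")
DIRECTIONS = ("up", "down")

DEFAULT_BIN_WIDTH = 0.01  # bits
_UNKNOWN_PENALTY = -(10 ** 9)


@dataclass
class ScanRegion:
    """One scannable sequence tied to an event, region role and direction."""

    event_id: str
    ase_type: str
    region_label: str
    interval: GenomicInterval
    sequence: str
    direction: str  # "up", "down" or "null"

    def __post_init__(self):
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"{self.event_id}/{self.region_label}: sequence length "
                f"{len(self.sequence)} != interval length {len(self.interval)}")

    @property
    def region_id(self) -> str:
        return f"{self.event_id}|{self.region_label}"


@dataclass
class EnrichmentResult:
    """Observed motif count vs the 100-control-set resampling null."""

    motif_id: str
    ase_type: str
    region_label: str
    direction: str
    observed_count: int
    control_mean: float
    control_sd: float
    zscore: float
    enriched: bool
    degenerate_null: bool = False


# ---------------------------------------------------------------------------
# exact PWM score p-values

def _binned_scores(motif: MotifModel,
                   bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Per-position log2-odds scores floored to integer bins."""
    cache = getattr(motif, "_bin_cache", None)
    if cache is not None and cache[0] == bin_width:
        return cache[1]
    s = np.log2(motif.pwm / motif.background)
    q = np.floor(s / bin_width).astype(np.int64)
    motif._bin_cache = (bin_width, q)
    return q


def pwm_tail_distribution(motif: MotifModel,
                          bin_width: float = DEFAULT_BIN_WIDTH
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact null distribution of the binned window score.

    Returns (support, pmf, tail) where support holds every reachable
    integer bin sum, pmf its probability under the background model, and
    tail[i] = P(score >= support[i]).  Computed by convolving the
    per-position score distributions (dynamic programming), which is exact
    in bin space.
    """
    q = _binned_scores(motif, bin_width)
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(len(motif)):
        row_lo = int(q[i].min())
        row_hi = int(q[i].max())
        new = np.zeros(cur.size + row_hi - row_lo)
        for letter in range(4):
            off = int(q[i, letter]) - row_lo
            new[off:off + cur.size] += motif.background[letter] * cur
        cur = new
        cur_lo += row_lo
    support = np.arange(cur_lo, cur_lo + cur.size)
    tail = np.cumsum(cur[::-1])[::-1]
    return support, cur, tail


def pwm_score_threshold(motif: MotifModel, pvalue_cutoff: float = 0.001,
                        bin_width: float = DEFAULT_BIN_WIDTH) -> float:
    """Smallest attainable binned score t with P(score >= t) <= cutoff.

    Stores the threshold on ``motif.score_threshold`` and returns it.
    When no attainable score is rare enough (an uninformative motif) the
    motif is unscannable and the threshold is ``math.inf``.
    """
    if not 0.0 < pvalue_cutoff < 1.0:
        raise ValueError("pvalue_cutoff must lie in (0, 1)")
    support, pmf, tail = pwm_tail_distribution(motif, bin_width)
    ok = (pmf > 0) & (tail <= pvalue_cutoff)
    if not ok.any():
        logger.warning("motif %s: no attainable score with tail <= %g; "
                       "flagged unscannable", motif.motif_id, pvalue_cutoff)
        motif.score_threshold = math.inf
        return math.inf
    thr = float(support[np.argmax(ok)])
    motif.score_threshold = thr
    return thr


def scan_sequence(motif: MotifModel, sequence: str | np.ndarray,
                  bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Start offsets of windows scoring at or above the motif threshold.

    Sense strand only; overlapping hits all count.  The sequence may be a
    string or a pre-encoded integer code array; letters outside ACGU never
    match.  A sequence shorter than the motif yields no hits.
    """
    if motif.score_threshold is None:
        raise ValueError(f"motif {motif.motif_id}: threshold not computed")
    L = len(motif)
    codes = encode_sequence(sequence) if isinstance(sequence, str) else sequence
    if math.isinf(motif.score_threshold) or codes.size < L:
        return np.empty(0, dtype=np.int64)
    q = _binned_scores(motif, bin_width)
    qx = np.hstack([q, np.full((L, 1), _UNKNOWN_PENALTY, dtype=np.int64)])
    codes = np.where(codes < 0, 4, codes)
    windows = sliding_window_view(codes, L)
    scores = qx[np.arange(L), windows].sum(axis=1)
    return np.nonzero(scores >= motif.score_threshold)[0]


# ---------------------------------------------------------------------------
# region construction

def classify_direction(dpsi: float, pvalue: float,
                       dpsi_cutoff: float = 0.05,
                       null_dpsi: float = 0.01,
                       null_p: float = 0.05) -> str | None:
    """Regulation direction of an event, or None when it is neither
    regulated nor clean enough for the null pool."""
    if dpsi > dpsi_cutoff:
        return "up"
    if dpsi < -dpsi_cutoff:
        return "down"
    if abs(dpsi) < null_dpsi and pvalue > null_p:
        return "null"
    return None


def build_scan_regions(events: list[SplicingEvent],
                       genome: dict[str, str],
                       flank: int = 200,
                       flank_mx: int = 100) -> list[ScanRegion]:
    """Extract flank and spliced-region sequences for each event.

    Alternative regions are extended ``flank`` nt on both sides (``flank_mx``
    for MX events).  Extraction is strand-aware: sequences from "-" strand
    events are reverse-complemented and the upstream flank is the
    genomic-right one.  Regions beyond the chromosome bounds are truncated
    with a warning.  Events whose (dpsi, pvalue) fall between the regulated
    and null definitions are dropped.
    """
    out: list[ScanRegion] = []
    for ev in events:
        direction = classify_direction(ev.dpsi, ev.pvalue)
        if direction is None:
            continue
        pad = flank_mx if ev.ase_type == "MX" else flank
        alt_items = [(k, v) for k, v in sorted(ev.regions.items())
                     if k.startswith("alt")]
        for alt_label, alt in alt_items:
            suffix = "" if len(alt_items) == 1 else f".{alt_label}"
            chrom_seq = genome[alt.chrom]
            bound = len(chrom_seq)
            left = GenomicInterval(alt.chrom, max(0, alt.start - pad),
                                   alt.start, alt.strand)
            right = GenomicInterval(alt.chrom, alt.end,
                                    min(bound, alt.end + pad), alt.strand)
            if alt.start - pad < 0 or alt.end + pad > bound:
                logger.warning("event %s: flank truncated at sequence bounds",
                               ev.event_id)
            if alt.strand == "+":
                parts = {"upstream_flank": left, "spliced_region": alt,
                         "downstream_flank": right}
            else:
                parts = {"upstream_flank": right, "spliced_region": alt,
                         "downstream_flank": left}
            for label, iv in parts.items():
                raw = chrom_seq[iv.start:iv.end]
                seq = (to_rna(raw) if iv.strand == "+"
                       else reverse_complement(raw))
                out.append(ScanRegion(
                    event_id=f"{ev.event_id}{suffix}", ase_type=ev.ase_type,
                    region_label=label, interval=iv, sequence=seq,
                    direction=direction))
    return out


# ---------------------------------------------------------------------------
# resampling null

def sample_control_sets(null_regions: list[ScanRegion],
                        target_regions: list[ScanRegion],
                        n_sets: int = 100,
                        rng: np.random.Generator | None = None,
                        n_nearest: int = 8) -> list[list[ScanRegion]]:
    """Draw ``n_sets`` control sets matching the target set in cardinality
    and (approximately) total sequence length.

    Each set has exactly as many sequences as the target and is drawn
    without replacement from the null pool by nearest-length sampling
    (each target length picks among the ``n_nearest`` closest remaining
    pool lengths).  A pool smaller than the target forces sampling with
    replacement within a set, with a prominent warning.
    """
    if not null_regions:
        raise ValueError("null pool is empty for this stratum")
    rng = rng if rng is not None else np.random.default_rng()
    pool_lens = np.array([len(r.sequence) for r in null_regions])
    target_lens = [len(r.sequence) for r in target_regions]
    replace = len(null_regions) < len(target_regions)
    if replace:
        logger.warning(
            "null pool (%d) smaller than target set (%d): sampling WITH "
            "replacement within control sets",
            len(null_regions), len(target_regions))
    sets = []
    for _ in range(n_sets):
        available = np.ones(len(null_regions), dtype=bool)
        chosen: list[ScanRegion] = []
        order = rng.permutation(len(target_lens))
        for ti in order:
            cand = np.nonzero(available)[0] if not replace \
                else np.arange(len(null_regions))
            d = np.abs(pool_lens[cand] - target_lens[ti])
            # all candidates tied with the k-th nearest are eligible, so
            # equal-length pools (flanks) still sample uniformly
            k = min(n_nearest, d.size) - 1
            d_k = np.partition(d, k)[k]
            nearest = cand[d <= d_k]
            pick = int(nearest[rng.integers(0, nearest.size)])
            chosen.append(null_regions[pick])
            if not replace:
                available[pick] = False
        sets.append(chosen)
    return sets


def enrichment_zscore(motif: MotifModel,
                      target_regions: list[ScanRegion],
                      control_sets: list[list[ScanRegion]],
                      z_cutoff: float = 1.96,
                      per_sequence: bool = False,
                      hit_cache: dict | None = None) -> EnrichmentResult:
    """Observed hit count normalized by the control-set mean and sd.

    ``per_sequence`` switches the count from total occurrences to the
    number of sequences with at least one hit.  A zero control sd makes z
    undefined; the result is then flagged degenerate and enrichment falls
    back to "observed exceeds every control set".
    """
    def count(regions: list[ScanRegion]) -> int:
        total = 0
        for r in regions:
            key = (motif.motif_id, id(r))
            if hit_cache is not None and key in hit_cache:
                n = hit_cache[key]
            else:
                n = scan_sequence(motif, r.sequence).size
                if hit_cache is not None:
                    hit_cache[key] = n
            total += min(n, 1) if per_sequence else n
        return total

    observed = count(target_regions)
    ctrl = np.array([count(cs) for cs in control_sets], dtype=float)
    mean = float(ctrl.mean())
    sd = float(ctrl.std(ddof=1))
    first = target_regions[0]
    if sd == 0.0:
        return EnrichmentResult(
            motif.motif_id, first.ase_type, first.region_label,
            first.direction, observed, mean, sd, math.nan,
            enriched=bool(observed > ctrl.max()), degenerate_null=True)
    z = (observed - mean) / sd
    return EnrichmentResult(
        motif.motif_id, first.ase_type, first.region_label, first.direction,
        observed, mean, sd, float(z), enriched=bool(z > z_cutoff))


# ---------------------------------------------------------------------------
# model / results facade

@dataclass
class MotifEnrichmentResults:
    """Enrichment z-scores, one row per motif x type x region x direction."""

    table: pd.DataFrame
    n_sets: int
    z_cutoff: float
    pvalue_cutoff: float

    @property
    def n_enriched(self) -> int:
        return int(self.table["enriched"].sum()) if len(self.table) else 0

    def enriched_motifs(self) -> list[str]:
        t = self.table
        return sorted(t[t["enriched"]]["motif_id"].unique()) if len(t) else []

    def summary(self) -> str:
        lines = [
            f"RBP motif enrichment ({self.n_sets} control sets, "
            f"z > {self.z_cutoff}, scan p < {self.pvalue_cutoff})",
            f"  cells evaluated: {len(self.table)}",
            f"  enriched cells:  {self.n_enriched}",
            f"  enriched motifs: {len(self.enriched_motifs())}",
        ]
        top = self.table[self.table["enriched"]].nlargest(
            min(5, self.n_enriched), "zscore")
        for _, r in top.iterrows():
            lines.append(
                f"  {r['motif_id']} {r['ase_type']}/{r['region_label']}"
                f"/{r['direction']}: z = {r['zscore']:.2f} "
                f"({r['observed_count']} vs {r['control_mean']:.1f}"
                f" +/- {r['control_sd']:.1f})")
        return "\n".join(lines)


class MotifEnrichmentModel:
    """Resampling-null motif enrichment over classified scan regions.

    Regions with direction "up"/"down" are the targets; "null" regions are
    the resampling pool, stratified by (event type, region label) so each
    control set is drawn from equivalent regions.
    """

    def __init__(self, regions: list[ScanRegion], motifs: list[MotifModel],
                 pvalue_cutoff: float = 0.001, n_sets: int = 100,
                 z_cutoff: float = 1.96, per_sequence: bool = False,
                 seed: int = 0):
        self.regions = regions
        self.motifs = motifs
        self.pvalue_cutoff = pvalue_cutoff
        self.n_sets = n_sets
        self.z_cutoff = z_cutoff
        self.per_sequence = per_sequence
        self.seed = seed

    def fit(self) -> MotifEnrichmentResults:
        for m in self.motifs:
            if m.score_threshold is None:
                pwm_score_threshold(m, self.pvalue_cutoff)
        strata: dict[tuple[str, str], dict[str, list[ScanRegion]]] = {}
        for r in self.regions:
            strata.setdefault((r.ase_type, r.region_label), {}) \
                  .setdefault(r.direction, []).append(r)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 5]))
        rows = []
        hit_cache: dict = {}
        for (ase_type, label), groups in sorted(strata.items()):
            null_pool = groups.get("null", [])
            for direction in DIRECTIONS:
                targets = groups.get(direction, [])
                if not targets or not null_pool:
                    continue
                control_sets = sample_control_sets(
                    null_pool, targets, self.n_sets, rng)
                for m in self.motifs:
                    res = enrichment_zscore(
                        m, targets, control_sets, self.z_cutoff,
                        self.per_sequence, hit_cache)
                    rows.append(vars(res))
        table = pd.DataFrame(rows, columns=[
            "motif_id", "ase_type", "region_label", "direction",
            "observed_count", "control_mean", "control_sd", "zscore",
            "enriched", "degenerate_null"])
        table.attrs["null_stratification"] = "ase_type,region_label"
        table.attrs["count_mode"] = ("per_sequence" if self.per_sequence
                                     else "total_occurrences")
        return MotifEnrichmentResults(table, self.n_sets, self.z_cutoff,
                                      self.pvalue_cutoff)
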