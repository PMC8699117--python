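"""Cohort-level association of event inclusion with marker expression,
patient groups and survival.

The cohort emulates the structure of a TCGA-style breast-cancer series:
ER+ tumors, ER- tumors and adjacent normals, with per-sample PSI values,
log2 marker (ESR1) expression and overall / disease-free survival.
Associations are non-parametric throughout: Spearman correlation of PSI
with the marker within ER+ tumors, Wilcoxon rank-sum group comparisons,
and Kaplan-Meier curves split at the cohort-median PSI with a log-rank
test (exact permutation null at small n).  Genomic binding evidence
(CLIP peaks) is consumed purely as intervals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as sps

from .datamodel import CohortSample, GenomicInterval, SplicingEvent
from .stats import benjamini_hochberg, spearman_rho, wilcoxon_ranksum

logger = logging.getLogger(__name__)

COMPARISONS = ("ERpos_vs_ERneg", "tumor_vs_normal", "high_vs_low_marker")


# ---------------------------------------------------------------------------
# PSI ~ marker correlation

def correlate_psi_with_marker(cohort: list[CohortSample],
                              event_ids: list[str],
                              min_rho: float = 0.10,
                              alpha: float = 0.05,
                              group: str = "ERpos_tumor",
                              signed: bool = False) -> pd.DataFrame:
    """Spearman correlation of each event's PSI with marker expression.

    Computed over the ``group`` samples with both values present.  The
    pass flag requires p < alpha and rho beyond ``min_rho`` (absolute by
    default; ``signed`` restricts to positive correlations, the preset
    used for marker-correlated regulators).  Events with constant PSI are
    skipped with a warning.
    """
    subset = [s for s in cohort if s.group == group]
    rows = []
    for e in event_ids:
        pairs = [(s.marker_expr, s.psi_by_event[e]) for s in subset
                 if e in s.psi_by_event]
        if len(pairs) < 4:
            logger.warning("event %s: < 4 complete pairs; skipped", e)
            continue
        x, y = map(np.array, zip(*pairs))
        if np.all(y == y[0]):
            logger.warning("event %s: constant PSI; rho undefined", e)
            continue
        rho, p = spearman_rho(x, y)
        ok = (p < alpha) and (rho > min_rho if signed
                              else abs(rho) >= min_rho)
        rows.append({"event_id": e, "n": len(pairs), "rho": rho,
                     "pvalue": p, "passed": ok})
    return pd.DataFrame(rows, columns=["event_id", "n", "rho",
                                       "pvalue", "passed"])


# ---------------------------------------------------------------------------
# group comparisons

def _marker_median_split(erpos: list[CohortSample]
                         ) -> tuple[list[CohortSample], list[CohortSample]]:
    med = float(np.median([s.marker_expr for s in erpos]))
    high = [s for s in erpos if s.marker_expr > med]
    low = [s for s in erpos if s.marker_expr <= med]  # ties go low
    return high, low


def compare_groups(cohort: list[CohortSample], event_ids: list[str],
                   dpsi_cutoff: float = 0.05,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Three per-event group comparisons of PSI distributions.

    (i) ER+ vs ER- tumors, (ii) ER+ tumors vs normal tissue, (iii) high-
    vs low-marker ER+ tumors (split at the ER+ median marker, ties low).
    dPSI is the first-group-minus-second-group mean; p is the two-sided
    Wilcoxon rank-sum test; the flag requires |dPSI| >= cutoff and
    p < alpha.  A group with fewer than 3 defined PSI values skips that
    comparison for that event.
    """
    erpos = [s for s in cohort if s.group == "ERpos_tumor"]
    erneg = [s for s in cohort if s.group == "ERneg_tumor"]
    normal = [s for s in cohort if s.group == "normal"]
    high, low = _marker_median_split(erpos) if erpos else ([], [])
    pairs = {"ERpos_vs_ERneg": (erpos, erneg),
             "tumor_vs_normal": (erpos, normal),
             "high_vs_low_marker": (high, low)}
    rows = []
    for e in event_ids:
        for comp, (ga, gb) in pairs.items():
            va = np.array([s.psi_by_event[e] for s in ga
                           if e in s.psi_by_event])
            vb = np.array([s.psi_by_event[e] for s in gb
                           if e in s.psi_by_event])
            if va.size < 3 or vb.size < 3:
                continue
            stat, p = wilcoxon_ranksum(va, vb)
            dpsi = float(va.mean() - vb.mean())
            rows.append({"event_id": e, "comparison": comp,
                         "n_a": va.size, "n_b": vb.size, "dpsi": dpsi,
                         "pvalue": p,
                         "flagged": bool(abs(dpsi) >= dpsi_cutoff
                                         and p < alpha)})
    df = pd.DataFrame(rows, columns=["event_id", "comparison", "n_a",
                                     "n_b", "dpsi", "pvalue", "flagged"])
    return df


def flagged_in_all_comparisons(comparisons: pd.DataFrame) -> list[str]:
    """Events significant in all three group comparisons."""
    if comparisons.empty:
        return []
    flags = comparisons.pivot_table(index="event_id", columns="comparison",
                                    values="flagged", aggfunc="first")
    full = flags.reindex(columns=list(COMPARISONS))
    return sorted(full.index[full.fillna(False).all(axis=1)])


# ---------------------------------------------------------------------------
# survival

def _logrank_chi2(times: np.ndarray, events: np.ndarray,
                  in_group1: np.ndarray) -> float:
    """Two-group log-rank chi-squared statistic (observed-minus-expected
    over distinct event times, hypergeometric variance)."""
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events.astype(bool)]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        d = ((times == t) & events.astype(bool)).sum()
        d1 = ((times == t) & events.astype(bool) & in_group1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e ** 2 / var)


@dataclass
class SurvivalResult:
    """Median-PSI split Kaplan-Meier comparison for one event."""

    event_id: str
    endpoint: str
    median_psi: float
    n_high: int
    n_low: int
    statistic: float
    pvalue: float
    exact: bool
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def median_split_survival(cohort: list[CohortSample], event_id: str,
                          endpoint: str = "OS",
                          exact_max_n: int = 10) -> SurvivalResult:
    """KM estimate and log-rank test for high vs low inclusion.

    Samples are split at the cohort-median PSI of the event (ties go to
    the low group).  With at most ``exact_max_n`` subjects and no
    censoring, the log-rank p-value is the exact permutation probability
    over all group relabelings; otherwise the chi-squared approximation.
    """
    if endpoint not in ("OS", "DFS"):
        raise ValueError("endpoint must be 'OS' or 'DFS'")
    prefix = endpoint.lower()
    usable = [s for s in cohort
              if event_id in s.psi_by_event
              and math.isfinite(getattr(s, f"{prefix}_time"))]
    if len(usable) < 10:
        raise ValueError(f"event {event_id}: need >= 10 samples with PSI "
                         f"and {endpoint} data, got {len(usable)}")
    psi = np.array([s.psi_by_event[event_id] for s in usable])
    med = float(np.median(psi))
    in_high = psi > med
    if in_high.all() or not in_high.any():
        raise ValueError(
            f"event {event_id}: constant PSI leaves one split group empty")
    times = np.array([getattr(s, f"{prefix}_time") for s in usable])
    flags = np.array([getattr(s, f"{prefix}_event") for s in usable],
                     dtype=bool)
    chi2 = _logrank_chi2(times, flags, in_high)
    n = len(usable)
    n1 = int(in_high.sum())
    exact = n <= exact_max_n and flags.all()
    if exact:
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            lab = np.zeros(n, dtype=bool)
            lab[list(combo)] = True
            if _logrank_chi2(times, flags, lab) >= chi2 - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        res = _lifelines_logrank(times[in_high], times[~in_high],
                                 flags[in_high], flags[~in_high])
        chi2 = float(res.test_statistic)
        p = float(res.p_value)
    curves = {}
    for label, mask in (("high", in_high), ("low", ~in_high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], flags[mask], label=label)
        curves[label] = kmf.survival_function_
    return SurvivalResult(event_id, endpoint, med, n1, n - n1,
                          chi2, p, exact, curves)


# ---------------------------------------------------------------------------
# list-overlap and interval-overlap statistics

def hypergeometric_overlap(list_a, list_b, universe) -> tuple[int, float]:
    """Exact upper-tail P(X >= |A & B|) under the hypergeometric law."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    a, b = set(list_a), set(list_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both lists must be subsets of the universe")
    k = len(a & b)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return k, min(1.0, p)


def overlap_with_peaks(events: list[SplicingEvent],
                       peaks: list[GenomicInterval],
                       extension: int = 200,
                       events_assembly: str = "synthetic",
                       peaks_assembly: str = "synthetic") -> pd.DataFrame:
    """Per-event overlap flags with binding-site peaks.

    Two strand-agnostic half-open flags per event: peak within the gene
    body (span of all event regions) and peak within the exon region(s)
    extended by ``extension`` bp.  Peaks and events must share a genome
    assembly name.
    """
    if events_assembly != peaks_assembly:
        raise ValueError(
            f"assembly mismatch: events on {events_assembly!r}, peaks on "
            f"{peaks_assembly!r}")
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    rows = []
    for ev in events:
        ivs = list(ev.regions.values())
        chrom = ivs[0].chrom
        tree = trees.get(chrom)
        gene_span = (min(iv.start for iv in ivs), max(iv.end for iv in ivs))
        in_gene = bool(tree.overlap(*gene_span)) if tree else False
        in_exon = False
        if tree:
            for alt in ev.alt_regions():
                ext = alt.extended(extension)
                if tree.overlap(ext.start, ext.end):
                    in_exon = True
                    break
        rows.append({"event_id": ev.event_id, "peak_in_gene": in_gene,
                     "peak_in_exon_ext": in_exon})
    return pd.DataFrame(rows, columns=["event_id", "peak_in_gene",
                                       "peak_in_exon_ext"])


# ---------------------------------------------------------------------------
# differential-expression plumbing

def de_plumbing(counts: pd.DataFrame, condition_map: dict[str, str],
                lfc_cutoff: float = 0.2, alpha: float = 0.05,
                floor: float = 10.0) -> pd.DataFrame:
    """Threshold-policy differential expression on a count matrix.

    Library-size-normalized counts; genes kept only when normalized counts
    exceed ``floor`` in every sample of at least one condition; log2 fold
    change of condition means with pseudocount 1; Welch test on log2
    counts; BH; flag at |log2FC| > ``lfc_cutoff`` and adj p < ``alpha``.
    This is a deliberately transparent stand-in for negative-binomial DE
    models — its contractual output is the threshold policy, not the model.
    """
    conds: dict[str, list[str]] = {}
    for s, c in condition_map.items():
        if s in counts.columns:
            conds.setdefault(c, []).append(s)
    if any(len(ss) < 2 for ss in conds.values()) or len(conds) != 2:
        raise ValueError("need two conditions with >= 2 samples each")
    samples = [s for ss in conds.values() for s in ss]
    mat = counts[samples].to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    norm = mat / lib * lib.mean()
    cond_names = sorted(conds)
    idx = {c: [samples.index(s) for s in conds[c]] for c in cond_names}
    keep = np.zeros(norm.shape[0], dtype=bool)
    for c in cond_names:
        keep |= (norm[:, idx[c]] > floor).all(axis=1)
    log_norm = np.log2(norm + 1.0)
    rows = []
    ctrl, other = ("control", "silenced") if "control" in conds \
        else (cond_names[0], cond_names[1])
    for gi in np.nonzero(keep)[0]:
        a = norm[gi, idx[other]]
        b = norm[gi, idx[ctrl]]
        lfc = math.log2((a.mean() + 1.0) / (b.mean() + 1.0))
        la, lb = log_norm[gi, idx[other]], log_norm[gi, idx[ctrl]]
        if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
            p = 1.0 if la.mean() == lb.mean() else 0.0
        else:
            p = float(sps.ttest_ind(la, lb, equal_var=False).pvalue)
        rows.append({"gene_id": counts.index[gi], "log2fc": lfc,
                     "pvalue": p})
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
    if not df.empty:
        df["adj_pvalue"] = benjamini_hochberg(df["pvalue"].to_numpy())
        df["flagged"] = ((df["log2fc"].abs() > lfc_cutoff)
                         & (df["adj_pvalue"] < alpha))
    else:
        df["adj_pvalue"] = []
        df["flagged"] = []
    return df


# ---------------------------------------------------------------------------
# model / results facade

@dataclass
class CohortAssociationResults:
    """Fitted cohort association: correlations, comparisons, survival."""

    correlations: pd.DataFrame
    comparisons: pd.DataFrame
    all_three: list[str]
    survival: list[SurvivalResult]

    def summary(self) -> str:
        lines = [
            "Cohort association",
            f"  events correlated with marker: "
            f"{int(self.correlations['passed'].sum())}"
            f" / {len(self.correlations)}",
            f"  events flagged in all three group comparisons: "
            f"{len(self.all_three)}",
        ]
        for sr in self.survival:
            lines.append(
                f"  {sr.event_id} {sr.endpoint}: log-rank chi2 = "
                f"{sr.statistic:.2f}, p = {sr.pvalue:.3g} "
                f"(high n={sr.n_high}, low n={sr.n_low})")
        return "\n".join(lines)


class CohortAssociationModel:
    """Associate event PSI with marker expression, groups and survival."""

    def __init__(self, cohort: list[CohortSample],
                 event_ids: list[str] | None = None,
                 min_rho: float = 0.10, alpha: float = 0.05,
                 dpsi_cutoff: float = 0.05):
        self.cohort = cohort
        if event_ids is None:
            event_ids = sorted({e for s in cohort for e in s.psi_by_event})
        self.event_ids = event_ids
        self.min_rho = min_rho
        self.alpha = alpha
        self.dpsi_cutoff = dpsi_cutoff

    @classmethod
    def from_file(cls, cohort_path, **kwargs) -> "CohortAssociationModel":
        from . import io as sio
        return cls(sio.read_cohort_table(cohort_path), **kwargs)

    def fit(self, survival_events: list[str] | None = None,
            endpoints: tuple[str, ...] = ("OS", "DFS")
            ) -> CohortAssociationResults:
        corr = correlate_psi_with_marker(
            self.cohort, self.event_ids, self.min_rho, self.alpha)
        comp = compare_groups(self.cohort, self.event_ids,
                              self.dpsi_cutoff, self.alpha)
        all3 = flagged_in_all_comparisons(comp)
        surv = []
        for e in (survival_events if survival_events is not None
                  else self.event_ids):
            for ep in endpoints:
                try:
                    surv.append(median_split_survival(self.cohort, e, ep))
                except ValueError as exc:
                    logger.warning("survival skipped: %s", exc)
        return CohortAssociationResults(corr, comp, all3, surv)
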