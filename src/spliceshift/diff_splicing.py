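"""Differential alternative-splicing analysis from junction counts.

PSI per sample is the length-normalized inclusion ratio
(I/l_inc) / (I/l_inc + S/l_skip); dPSI is mean PSI(silenced) minus mean
PSI(control), so positive dPSI means higher inclusion after silencing.
Events are prefiltered for junction support (>= 10 reads in >= 2 samples
of each condition) and called significant when the BH-adjusted p-value of
a replicate-level Welch test on arcsine-square-root transformed PSI is at
most alpha and |dPSI| >= 0.05.  The Welch test is a transparent stand-in
for likelihood-based splicing callers and is named in the output metadata
so its results are never conflated with theirs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ASE_TYPES, SplicingEvent
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)


def compute_psi(event: SplicingEvent,
                samples: list[str] | None = None) -> dict[str, float]:
    """Per-sample length-normalized PSI; NaN where inc + skip == 0."""
    samples = samples if samples is not None else event.samples
    return {s: event.psi(s) for s in samples}


def filter_events(events: list[SplicingEvent],
                  condition_map: dict[str, str],
                  min_reads: int = 10,
                  min_samples: int = 2) -> list[SplicingEvent]:
    """Keep events with >= min_reads supporting reads (inc + skip) in at
    least ``min_samples`` samples of EACH condition.  Idempotent and
    order-independent."""
    conds: dict[str, list[str]] = {}
    for s, c in condition_map.items():
        conds.setdefault(c, []).append(s)
    if len(conds) < 2:
        raise ValueError("both conditions must be present")
    kept = []
    for ev in events:
        ok = True
        for ss in conds.values():
            n_q = sum(1 for s in ss
                      if ev.inc_counts[s] + ev.skip_counts[s] >= min_reads)
            if n_q < min_samples:
                ok = False
                break
        if ok:
            kept.append(ev)
    return kept


def _asin_sqrt(x: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def test_differential_splicing(events: list[SplicingEvent],
                               condition_map: dict[str, str],
                               dpsi_cutoff: float = 0.05,
                               alpha: float = 0.05) -> pd.DataFrame:
    """dPSI plus a Welch test on arcsine-root PSI, BH across events.

    Events with fewer than two defined PSI replicates in either condition
    are skipped with a warning.  Results are written back onto the event
    objects (dpsi, pvalue, adj_pvalue) and returned as a table.
    """
    ctrl = sorted(s for s, c in condition_map.items() if c == "control")
    sil = sorted(s for s, c in condition_map.items() if c == "silenced")
    rows = []
    for ev in events:
        psi_c = np.array([ev.psi(s) for s in ctrl])
        psi_s = np.array([ev.psi(s) for s in sil])
        pc = psi_c[~np.isnan(psi_c)]
        ps = psi_s[~np.isnan(psi_s)]
        if pc.size < 2 or ps.size < 2:
            logger.warning("event %s: < 2 defined PSI replicates in a "
                           "condition; skipped", ev.event_id)
            continue
        dpsi = float(ps.mean() - pc.mean())
        ta, tb = _asin_sqrt(pc), _asin_sqrt(ps)
        if ta.var(ddof=1) == 0 and tb.var(ddof=1) == 0:
            p = 1.0 if ta.mean() == tb.mean() else 0.0
        else:
            p = float(sps.ttest_ind(ta, tb, equal_var=False).pvalue)
        ev.dpsi = dpsi
        ev.pvalue = p
        rows.append({"event_id": ev.event_id, "gene_id": ev.gene_id,
                     "ase_type": ev.ase_type,
                     "psi_control": float(pc.mean()),
                     "psi_silenced": float(ps.mean()),
                     "dpsi": dpsi, "pvalue": p})
    df = pd.DataFrame(rows, columns=["event_id", "gene_id", "ase_type",
                                     "psi_control", "psi_silenced",
                                     "dpsi", "pvalue"])
    if not df.empty:
        df["adj_pvalue"] = benjamini_hochberg(df["pvalue"].to_numpy())
        df["significant"] = ((df["adj_pvalue"] <= alpha)
                             & (df["dpsi"].abs() >= dpsi_cutoff))
    else:
        df["adj_pvalue"] = []
        df["significant"] = []
    adj = dict(zip(df["event_id"], df["adj_pvalue"]))
    for ev in events:
        if ev.event_id in adj:
            ev.adj_pvalue = float(adj[ev.event_id])
    df.attrs["test"] = "welch_on_arcsine_sqrt_PSI"
    df.attrs["dpsi_cutoff"] = dpsi_cutoff
    df.attrs["alpha"] = alpha
    return df


def summarize_by_type(flagged: pd.DataFrame) -> pd.DataFrame:
    """Counts, percentages and dPSI direction per event type."""
    sig = flagged[flagged["significant"]] if "significant" in flagged else flagged
    total = len(sig)
    rows = []
    for t in ASE_TYPES:
        sub = sig[sig["ase_type"] == t]
        rows.append({
            "ase_type": t, "n": len(sub),
            "percent": 100.0 * len(sub) / total if total else 0.0,
            "n_dpsi_positive": int((sub["dpsi"] > 0).sum()),
            "mean_dpsi": float(sub["dpsi"].mean()) if len(sub) else 0.0,
        })
    df = pd.DataFrame(rows)
    df.attrs["frac_dpsi_positive"] = (
        float((sig["dpsi"] > 0).mean()) if total else math.nan)
    return df


@dataclass
class DifferentialSplicingResults:
    """Fitted differential-splicing call set."""

    table: pd.DataFrame
    by_type: pd.DataFrame
    events: list[SplicingEvent]
    dpsi_cutoff: float
    alpha: float
    n_input: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum()) if len(self.table) else 0

    def significant_events(self) -> list[SplicingEvent]:
        sig = set(self.table[self.table["significant"]]["event_id"])
        return [e for e in self.events if e.event_id in sig]

    def null_events(self, dpsi_max: float = 0.01,
                    p_min: float = 0.05) -> list[SplicingEvent]:
        """Non-regulated events (|dPSI| < 0.01 and p > 0.05): the pool the
        motif-enrichment null is resampled from."""
        keep = set(self.table[(self.table["dpsi"].abs() < dpsi_max)
                              & (self.table["pvalue"] > p_min)]["event_id"])
        return [e for e in self.events if e.event_id in keep]

    def summary(self) -> str:
        frac_pos = self.by_type.attrs.get("frac_dpsi_positive", math.nan)
        lines = [
            "Differential splicing (Welch on arcsine-root PSI, BH)",
            f"  events in:            {self.n_input}",
            f"  events after filter:  {len(self.events)}",
            f"  significant events:   {self.n_significant} "
            f"(|dPSI| >= {self.dpsi_cutoff}, adj p <= {self.alpha})",
            f"  fraction dPSI > 0:    {frac_pos:.2f}",
        ]
        for _, r in self.by_type.iterrows():
            lines.append(f"  {r['ase_type']:<4} {int(r['n']):>5}  "
                         f"({r['percent']:.0f}%)")
        return "\n".join(lines)


class DifferentialSplicingModel:
    """Differential-splicing analysis over a two-condition event table."""

    def __init__(self, events: list[SplicingEvent],
                 condition_map: dict[str, str],
                 min_reads: int = 10, min_samples: int = 2,
                 dpsi_cutoff: float = 0.05, alpha: float = 0.05):
        self.events = events
        self.condition_map = condition_map
        self.min_reads = min_reads
        self.min_samples = min_samples
        self.dpsi_cutoff = dpsi_cutoff
        self.alpha = alpha

    @classmethod
    def from_files(cls, events_path, samples_path, **kwargs
                   ) -> "DifferentialSplicingModel":
        from . import io as sio
        return cls(sio.read_event_table(events_path),
                   sio.read_condition_map(samples_path), **kwargs)

    def fit(self) -> DifferentialSplicingResults:
        n_input = len(self.events)
        kept = filter_events(self.events, self.condition_map,
                             self.min_reads, self.min_samples)
        table = test_differential_splicing(kept, self.condition_map,
                                           self.dpsi_cutoff, self.alpha)
        by_type = summarize_by_type(table)
        return DifferentialSplicingResults(table, by_type, kept,
                                           self.dpsi_cutoff, self.alpha,
                                           n_input)
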