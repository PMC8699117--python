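"""Isoform-switch detection from isoform fractions.

An isoform's fraction IF = TPM_iso / TPM_gene is its share of the parent
gene's expression; dIF = IF(silenced) - IF(control).  A switch is a
significant, reciprocal change in usage within a gene.  Expression filters
follow the standard practice for this analysis: genes under 1 TPM in both
condition means and isoforms contributing under 1% of the gene in both
conditions are excluded before testing.

Significance uses a Welch two-sample test on per-replicate IF values with
BH correction across isoforms — a transparent replicate-level stand-in for
the likelihood machinery of dedicated switch tools, and flagged as such in
the output metadata.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import GenomicInterval, IsoformQuant
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

LENGTH_FEATURES = ("orf_length", "utr5_length", "utr3_length")
COUNT_FEATURES = ("n_domains",)
FLAG_FEATURES = ("intron_retention", "nmd_insensitivity", "coding")

SWITCH_CLASSES = ("ES", "MES", "A5", "A3", "IR", "ATSS", "ATTS")


def _condition_samples(condition_map: dict[str, str]) -> dict[str, list[str]]:
    conds: dict[str, list[str]] = {"control": [], "silenced": []}
    for s, c in condition_map.items():
        if c not in conds:
            raise ValueError(f"unknown condition {c!r} for sample {s!r}")
        conds[c].append(s)
    for c, ss in conds.items():
        if len(ss) < 2:
            raise ValueError(f"condition {c!r} needs >= 2 samples")
    return conds


def compute_isoform_fractions(quants: list[IsoformQuant],
                              condition_map: dict[str, str],
                              min_gene_tpm: float = 1.0,
                              min_if: float = 0.01) -> pd.DataFrame:
    """Per-replicate and per-condition isoform fractions with dIF.

    Replicate IF is TPM_iso / TPM_gene with the gene TPM taken as the sum
    of its isoforms' TPM in that replicate; a zero gene TPM leaves that
    replicate's IF missing.  Genes whose mean TPM is below ``min_gene_tpm``
    in both conditions, and isoforms whose mean IF is below ``min_if`` in
    both conditions, are excluded.
    """
    conds = _condition_samples(condition_map)
    samples = conds["control"] + conds["silenced"]
    by_gene: dict[str, list[IsoformQuant]] = {}
    for q in quants:
        by_gene.setdefault(q.gene_id, []).append(q)
    rows = []
    for gene_id, isoforms in by_gene.items():
        gene_tpm = {s: sum(q.tpm[s] for q in isoforms) for s in samples}
        gene_means = {c: float(np.mean([gene_tpm[s] for s in ss]))
                      for c, ss in conds.items()}
        if all(v < min_gene_tpm for v in gene_means.values()):
            continue
        for q in isoforms:
            ifs = {s: (q.tpm[s] / gene_tpm[s]) if gene_tpm[s] > 0 else np.nan
                   for s in samples}
            means = {}
            for c, ss in conds.items():
                vals = [ifs[s] for s in ss if not np.isnan(ifs[s])]
                means[c] = float(np.mean(vals)) if vals else np.nan
            if all(not np.isnan(means[c]) and means[c] < min_if
                   for c in conds):
                continue
            row = {"isoform_id": q.isoform_id, "gene_id": gene_id,
                   "if_control": means["control"],
                   "if_silenced": means["silenced"],
                   "dif": means["silenced"] - means["control"]}
            row.update({f"if__{s}": ifs[s] for s in samples})
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["condition_samples"] = conds
    return df


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def test_switches(records: pd.DataFrame, dif_cutoff: float = 0.1,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Welch test on replicate IFs, BH across isoforms, dual cutoff flag.

    An isoform is flagged as switching iff its BH-adjusted p-value is at
    most ``alpha`` and |dIF| >= ``dif_cutoff``.
    """
    conds = records.attrs["condition_samples"]
    out = records.copy()
    pvals = []
    for _, row in records.iterrows():
        a = np.array([row[f"if__{s}"] for s in conds["control"]], dtype=float)
        b = np.array([row[f"if__{s}"] for s in conds["silenced"]], dtype=float)
        pvals.append(_welch_p(a, b))
    out["pvalue"] = pvals
    out["adj_pvalue"] = benjamini_hochberg(out["pvalue"].to_numpy())
    out["significant"] = ((out["adj_pvalue"] <= alpha)
                          & (out["dif"].abs() >= dif_cutoff)).fillna(False)
    out.attrs["condition_samples"] = conds
    out.attrs["test"] = "welch_on_replicate_IF"
    out.attrs["dif_cutoff"] = dif_cutoff
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# switch consequences

def _feature_deltas(up: IsoformQuant, down: IsoformQuant,
                    rel_tol: float = 0.05) -> dict[str, str]:
    """Gain/loss/none per feature from the up-isoform's perspective.

    Length features count as changed only beyond ``rel_tol`` relative
    difference, so annotation jitter of a few nucleotides is ignored.
    """
    deltas: dict[str, str] = {}
    for f in LENGTH_FEATURES:
        a, b = getattr(up.annotation, f), getattr(down.annotation, f)
        denom = max(abs(a), abs(b))
        if denom == 0 or abs(a - b) / denom <= rel_tol:
            deltas[f] = "none"
        else:
            deltas[f] = "gain" if a > b else "loss"
    for f in COUNT_FEATURES:
        a, b = getattr(up.annotation, f), getattr(down.annotation, f)
        deltas[f] = "none" if a == b else ("gain" if a > b else "loss")
    flag_of = {"intron_retention": "has_intron_retention",
               "nmd_insensitivity": "nmd_sensitive",
               "coding": "coding"}
    for f in FLAG_FEATURES:
        a = getattr(up.annotation, flag_of[f])
        b = getattr(down.annotation, flag_of[f])
        if f == "nmd_insensitivity":
            a, b = (not a), (not b)  # insensitivity is the positive trait
        if a == b:
            deltas[f] = "none"
        else:
            deltas[f] = "gain" if a and not b else "loss"
    return deltas


def annotate_consequences(flagged: pd.DataFrame,
                          quants: list[IsoformQuant],
                          rel_tol: float = 0.05) -> pd.DataFrame:
    """Feature gains/losses for every significant up/down pair per gene."""
    by_id = {q.isoform_id: q for q in quants}
    sig = flagged[flagged["significant"]]
    rows = []
    for gene_id, grp in sig.groupby("gene_id"):
        ups = grp[grp["dif"] > 0]["isoform_id"].tolist()
        downs = grp[grp["dif"] < 0]["isoform_id"].tolist()
        for u, d in itertools.product(ups, downs):
            deltas = _feature_deltas(by_id[u], by_id[d], rel_tol)
            row = {"gene_id": gene_id, "up_isoform": u, "down_isoform": d}
            row.update(deltas)
            row["informative"] = any(v != "none" for v in deltas.values())
            rows.append(row)
    cols = (["gene_id", "up_isoform", "down_isoform"]
            + list(LENGTH_FEATURES) + list(COUNT_FEATURES)
            + list(FLAG_FEATURES) + ["informative"])
    return pd.DataFrame(rows, columns=cols)


def consequence_enrichment(consequences: pd.DataFrame) -> pd.DataFrame:
    """Per-feature gain fraction with an exact binomial test against 0.5.

    Only pairs with a non-"none" delta for the feature are informative;
    features with no informative pair are omitted.  BH across features.
    """
    rows = []
    features = LENGTH_FEATURES + COUNT_FEATURES + FLAG_FEATURES
    for f in features:
        if consequences.empty:
            continue
        counts = consequences[f].value_counts()
        n_gain = int(counts.get("gain", 0))
        n_loss = int(counts.get("loss", 0))
        n = n_gain + n_loss
        if n == 0:
            continue
        p = float(sps.binomtest(n_gain, n, 0.5).pvalue)
        rows.append({"feature": f, "n_gain": n_gain, "n_loss": n_loss,
                     "fraction_gain": n_gain / n, "pvalue": p})
    df = pd.DataFrame(rows,
                      columns=["feature", "n_gain", "n_loss",
                               "fraction_gain", "pvalue"])
    if not df.empty:
        df["adj_pvalue"] = benjamini_hochberg(df["pvalue"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# ASE classification of switch pairs

def _sorted_exons(exons: list[GenomicInterval]) -> list[tuple[int, int]]:
    return sorted((e.start, e.end) for e in exons)


def classify_pair(up_exons: list[GenomicInterval],
                  down_exons: list[GenomicInterval]) -> set[str]:
    """Classify the structural difference between two exon chains.

    Returns a subset of {ES, MES, A5, A3, IR, ATSS, ATTS}; an exon chain
    pair may yield multiple classes.  Splice-site sides are strand-aware:
    on "+" an exon's end is its donor (5' splice site), on "-" its start.
    """
    strand = up_exons[0].strand if up_exons else "+"
    a = _sorted_exons(up_exons)
    b = _sorted_exons(down_exons)
    if a == b:
        logger.warning("identical exon chains; no switch class assigned")
        return set()
    classes: set[str] = set()

    def terminal_label(is_left_end: bool) -> str:
        # genomic-left terminus is the TSS on "+", the TTS on "-"
        if strand == "+":
            return "ATSS" if is_left_end else "ATTS"
        return "ATTS" if is_left_end else "ATSS"

    def splice_site_label(boundary_is_end: bool) -> str:
        # exon end = donor on "+": a shifted donor is an alternative 5' site
        if strand == "+":
            return "A5" if boundary_is_end else "A3"
        return "A3" if boundary_is_end else "A5"

    for chain, other in ((a, b), (b, a)):
        other_set = set(other)
        # intron retention: one exon of `chain` spans two consecutive
        # exons of `other` plus the intervening intron
        for e in chain:
            if e in other_set:
                continue
            for f, g in zip(other, other[1:]):
                if f[0] == e[0] and g[1] == e[1]:
                    classes.add("IR")
        # skipped exons: internal exons of `chain` absent from and not
        # overlapping anything in `other`
        unique_internal = []
        for i, e in enumerate(chain):
            if e in other_set:
                continue
            overlapping = [o for o in other if o[0] < e[1] and e[0] < o[1]]
            if not overlapping:
                if 0 < i < len(chain) - 1:
                    unique_internal.append(i)
                elif i == 0:
                    classes.add(terminal_label(is_left_end=True))
                else:
                    classes.add(terminal_label(is_left_end=False))
            else:
                for o in overlapping:
                    if o[0] == e[0] and o[1] != e[1]:
                        at_terminus = (e == chain[-1] and o == other[-1])
                        classes.add("ATTS" if at_terminus and strand == "+"
                                    else "ATSS" if at_terminus
                                    else splice_site_label(True))
                    elif o[1] == e[1] and o[0] != e[0]:
                        at_terminus = (e == chain[0] and o == other[0])
                        classes.add("ATSS" if at_terminus and strand == "+"
                                    else "ATTS" if at_terminus
                                    else splice_site_label(False))
        if unique_internal:
            runs = np.split(np.array(unique_internal),
                            np.where(np.diff(unique_internal) > 1)[0] + 1)
            for run in runs:
                classes.add("MES" if len(run) > 1 else "ES")
    return classes


def classify_switch_ases(flagged: pd.DataFrame,
                         exon_chains: dict[str, list[GenomicInterval]]
                         ) -> pd.DataFrame:
    """Per-class counts over all significant up/down pairs with structures."""
    sig = flagged[flagged["significant"]]
    counts = {c: 0 for c in SWITCH_CLASSES}
    for gene_id, grp in sig.groupby("gene_id"):
        ups = grp[grp["dif"] > 0]["isoform_id"]
        downs = grp[grp["dif"] < 0]["isoform_id"]
        for u, d in itertools.product(ups, downs):
            if u not in exon_chains or d not in exon_chains:
                continue
            for c in classify_pair(exon_chains[u], exon_chains[d]):
                counts[c] += 1
    total = sum(counts.values())
    return pd.DataFrame([
        {"switch_class": c, "n_pairs": n,
         "fraction": n / total if total else 0.0}
        for c, n in counts.items()])


# ---------------------------------------------------------------------------
# model / results facade

@dataclass
class IsoformSwitchResults:
    """Fitted switch analysis: per-isoform records plus consequence tables."""

    records: pd.DataFrame
    consequences: pd.DataFrame
    enrichment: pd.DataFrame
    class_counts: pd.DataFrame | None
    dif_cutoff: float
    alpha: float

    @property
    def n_switching(self) -> int:
        return int(self.records["significant"].sum())

    @property
    def switching_genes(self) -> list[str]:
        sig = self.records[self.records["significant"]]
        return sorted(sig["gene_id"].unique())

    def summary(self) -> str:
        lines = [
            "Isoform switch analysis (Welch test on replicate IF, BH)",
            f"  isoforms tested:      {len(self.records)}",
            f"  switching isoforms:   {self.n_switching} "
            f"(|dIF| >= {self.dif_cutoff}, adj p <= {self.alpha})",
            f"  switching genes:      {len(self.switching_genes)}",
            f"  up/down pairs:        {len(self.consequences)}",
        ]
        for _, r in self.enrichment.iterrows():
            lines.append(
                f"  {r['feature']:<18} gain {r['n_gain']:>3} / loss "
                f"{r['n_loss']:>3}  frac {r['fraction_gain']:.2f}  "
                f"adj p {r['adj_pvalue']:.3g}")
        return "\n".join(lines)


class IsoformSwitchModel:
    """Switch analysis over a two-condition isoform quantification.

    Parameters
    ----------
    quants : list of IsoformQuant
    condition_map : sample -> {"control", "silenced"}
    dif_cutoff : minimum |dIF| for a switch (0.1 by default; 0.05 is the
        common permissive alternative and is equally supported)
    alpha : BH-adjusted significance level
    """

    def __init__(self, quants: list[IsoformQuant],
                 condition_map: dict[str, str],
                 dif_cutoff: float = 0.1, alpha: float = 0.05,
                 min_gene_tpm: float = 1.0, min_if: float = 0.01):
        self.quants = quants
        self.condition_map = condition_map
        self.dif_cutoff = dif_cutoff
        self.alpha = alpha
        self.min_gene_tpm = min_gene_tpm
        self.min_if = min_if

    @classmethod
    def from_files(cls, iso_path, samples_path, annotation_path=None,
                   **kwargs) -> "IsoformSwitchModel":
        from . import io as sio
        cond = sio.read_condition_map(samples_path)
        tpm = sio.read_expression_table(iso_path, kind="isoform",
                                        condition_map=cond)
        ann = (sio.read_annotation_table(annotation_path)
               if annotation_path else None)
        return cls(sio.quants_from_frames(tpm, annotations=ann), cond,
                   **kwargs)

    def fit(self, exon_chains: dict[str, list[GenomicInterval]] | None = None
            ) -> IsoformSwitchResults:
        records = compute_isoform_fractions(
            self.quants, self.condition_map,
            min_gene_tpm=self.min_gene_tpm, min_if=self.min_if)
        flagged = test_switches(records, self.dif_cutoff, self.alpha)
        consequences = annotate_consequences(flagged, self.quants)
        enrichment = consequence_enrichment(consequences)
        class_counts = (classify_switch_ases(flagged, exon_chains)
                        if exon_chains else None)
        return IsoformSwitchResults(flagged, consequences, enrichment,
                                    class_counts, self.dif_cutoff, self.alpha)
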