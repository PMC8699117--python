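"""Synthetic inputs with known ground truth.

Every pipeline input can be generated here: a two-condition isoform
experiment with planted usage switches, alternative-splicing events with
beta-binomially overdispersed junction counts, event-region sequences with
motif occurrences planted at an elevated rate, and a pseudo-cohort with a
planted PSI-marker rank correlation and a planted hazard difference.  All
generators are deterministic functions of ``SimulationConfig.seed``.

Default sizes are desk-scale: 500 genes, 3 replicates per condition,
~200 splicing events in the field-typical type composition, and a
200-sample cohort preserving the 773:192:113 proportions of ER+ tumor,
ER- tumor and adjacent-normal samples reported for the TCGA BRCA cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist, norm

from .datamodel import (RNA_ALPHABET, CohortSample, GenomicInterval,
                        IsoformAnnotation, IsoformQuant, MotifModel,
                        SplicingEvent)

__all__ = ["SimulationConfig", "simulate_isoform_experiment",
           "simulate_ase_counts", "simulate_region_sequences",
           "simulate_cohort", "make_random_motifs"]


@dataclass
class SimulationConfig:
    """Knobs for every generator; one seed drives them all."""

    seed: int = 0
    # isoform experiment
    n_genes: int = 500
    isoforms_per_gene: tuple[int, int] = (2, 4)
    n_replicates: int = 3
    switch_fraction: float = 0.1
    planted_dif: float = 0.3
    replicate_sdlog: float = 0.06  # log-normal replicate noise on TPM
    # splicing events (counts follow the type mix reported for ERalpha
    # depletion: ES-dominated, then IR, A3, A5, MX)
    n_events_per_type: dict[str, int] = field(
        default_factory=lambda: {"ES": 130, "IR": 35, "A3": 18,
                                 "A5": 11, "MX": 9})
    diff_fraction: float = 0.2
    planted_dpsi: float = 0.2
    frac_dpsi_positive: float = 0.7
    junction_depth: float = 300.0
    overdispersion: float = 0.002  # beta-binomial rho
    low_coverage_fraction: float = 0.05
    # region sequences
    motif_plant_rate: float = 3.0  # planted occurrences per kb, regulated regions
    flank_length: int = 200
    flank_length_mx: int = 100
    # cohort (group sizes scale 773:192:113 down to 200 samples)
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"ERpos_tumor": 143, "ERneg_tumor": 36,
                                 "normal": 21})
    planted_rho: float = 0.4
    planted_group_dpsi: float = 0.2
    planted_hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 1500.0   # per day
    censor_low: float = 200.0
    censor_high: float = 3000.0   # ~40% censoring at the default hazard
    psi_missing_rate: float = 0.05
    n_planted_cohort_events: int = 3

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream per pipeline stage, all derived from seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))

    def validate(self) -> None:
        lo, hi = self.isoforms_per_gene
        if self.switch_fraction > 0 and hi < 2:
            raise ValueError("switch_fraction > 0 needs isoforms_per_gene >= 2")
        for name in ("switch_fraction", "diff_fraction", "frac_dpsi_positive",
                     "psi_missing_rate", "low_coverage_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must lie in [0, 1)")
        if not -1.0 < self.planted_rho < 1.0:
            raise ValueError("planted_rho must lie in (-1, 1)")


def _sample_names(n_replicates: int) -> tuple[list[str], dict[str, str]]:
    samples = [f"control_{i+1}" for i in range(n_replicates)] + \
              [f"silenced_{i+1}" for i in range(n_replicates)]
    cond = {s: s.rsplit("_", 1)[0] for s in samples}
    return samples, cond


def _beta_binomial(rng, n, mean, rho):
    """Beta-binomial draw with mean ``mean`` and intra-class rho."""
    mean = np.clip(mean, 1e-6, 1 - 1e-6)
    if rho <= 0:
        return rng.binomial(n, mean)
    a = mean * (1 - rho) / rho
    b = (1 - mean) * (1 - rho) / rho
    return rng.binomial(n, rng.beta(a, b))


# ---------------------------------------------------------------------------
# isoform experiment

def simulate_isoform_experiment(config: SimulationConfig
                                ) -> tuple[list[IsoformQuant], pd.DataFrame]:
    """Two-condition isoform expression with planted usage switches.

    For ``switch_fraction`` of genes two isoforms exchange a usage share of
    ``planted_dif`` between conditions while the gene-level TPM stays
    constant; replicate noise is log-normal with mean-corrected scale.  The
    truth table records per isoform whether it switches and its true dIF.
    """
    config.validate()
    rng = config.rng(1)
    samples, cond = _sample_names(config.n_replicates)
    lo, hi = config.isoforms_per_gene
    n_switch = int(round(config.switch_fraction * config.n_genes))
    quants: list[IsoformQuant] = []
    truth_rows = []
    noise_mu = -0.5 * config.replicate_sdlog ** 2
    for g in range(config.n_genes):
        gene_id = f"G{g:05d}"
        k = int(rng.integers(max(lo, 2) if g < n_switch else lo, hi + 1))
        # switches are planted in clearly expressed genes; the rest span
        # the full dynamic range including sub-threshold expression
        lo_log = 0.5 if g < n_switch else -0.5
        gene_tpm = 10.0 ** rng.uniform(lo_log, 3.0)
        usage = rng.dirichlet(np.full(k, 2.0))
        usage_sil = usage.copy()
        true_dif = np.zeros(k)
        is_switch = g < n_switch
        if is_switch:
            d = config.planted_dif
            # the swapping pair shares pair_mass, leaving headroom for the
            # shift; any further isoforms split the remainder evenly
            pair_mass = 1.0 if k == 2 else 0.8
            usage = np.full(k, (1.0 - pair_mass) / max(1, k - 2))
            usage[0], usage[1] = (pair_mass + d) / 2, (pair_mass - d) / 2
            usage_sil = usage.copy()
            usage_sil[0] -= d
            usage_sil[1] += d
            true_dif[0], true_dif[1] = -d, d
        for i in range(k):
            iso_id = f"{gene_id}.{i+1}"
            tpm = {}
            counts = {}
            for s in samples:
                u = usage[i] if cond[s] == "control" else usage_sil[i]
                noise = rng.lognormal(noise_mu, config.replicate_sdlog) \
                    if config.replicate_sdlog > 0 else 1.0
                val = gene_tpm * u * noise
                tpm[s] = val
                counts[s] = int(round(val * 30.0))
            ann = IsoformAnnotation(
                orf_length=int(rng.integers(300, 3000)),
                utr5_length=int(rng.integers(50, 500)),
                utr3_length=int(rng.integers(100, 2000)),
                n_domains=int(rng.integers(0, 8)),
                has_intron_retention=bool(rng.random() < 0.1),
                coding=bool(rng.random() < 0.9),
                nmd_sensitive=bool(rng.random() < 0.15),
            )
            quants.append(IsoformQuant(iso_id, gene_id, tpm, counts, ann))
            truth_rows.append({"isoform_id": iso_id, "gene_id": gene_id,
                               "is_switch": is_switch and i < 2,
                               "true_dif": true_dif[i],
                               "gene_tpm": gene_tpm})
    return quants, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# splicing events

def simulate_ase_counts(config: SimulationConfig
                        ) -> tuple[list[SplicingEvent], pd.DataFrame]:
    """Junction counts for all five event types with planted dPSI.

    Per event and sample the total junction depth is Poisson and the
    inclusion count beta-binomial around the length-weighted inclusion
    probability, so the length-normalized PSI estimator is consistent for
    the true PSI.  ``diff_fraction`` of each type carries a true dPSI of
    ``planted_dpsi`` whose sign is positive with ``frac_dpsi_positive``.
    """
    config.validate()
    rng = config.rng(2)
    samples, cond = _sample_names(config.n_replicates)
    events: list[SplicingEvent] = []
    truth_rows = []
    cursor = 10_000
    for ase_type, n_ev in config.n_events_per_type.items():
        n_diff = int(round(config.diff_fraction * n_ev))
        for j in range(n_ev):
            event_id = f"{ase_type}_{j:04d}"
            gene_id = f"EG{len(events):05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            alt_len = int(rng.integers(80, 301))
            chrom = "chrS"
            regions = {
                "upstream_exon": GenomicInterval(
                    chrom, cursor - 150, cursor - 30, strand),
                "alt" if ase_type != "MX" else "alt1": GenomicInterval(
                    chrom, cursor, cursor + alt_len, strand),
                "downstream_exon": GenomicInterval(
                    chrom, cursor + alt_len + 400, cursor + alt_len + 520, strand),
            }
            if ase_type == "MX":
                regions["alt2"] = GenomicInterval(
                    chrom, cursor + alt_len + 100, cursor + alt_len + 200, strand)
            cursor += alt_len + 2000
            psi_c = rng.uniform(0.2, 0.8)
            is_diff = j < n_diff
            if is_diff:
                sign = 1.0 if rng.random() < config.frac_dpsi_positive else -1.0
                psi_s = float(np.clip(psi_c + sign * config.planted_dpsi,
                                      0.02, 0.98))
            else:
                psi_s = psi_c
            depth = config.junction_depth
            if rng.random() < config.low_coverage_fraction:
                depth = 4.0
            inc_eff, skip_eff = 2, 1
            inc_counts, skip_counts = {}, {}
            for s in samples:
                true_psi = psi_c if cond[s] == "control" else psi_s
                # inclusion read probability reflects junction multiplicity
                p_inc = true_psi * inc_eff / (true_psi * inc_eff
                                              + (1 - true_psi) * skip_eff)
                total = int(rng.poisson(depth))
                inc = int(_beta_binomial(rng, total, p_inc,
                                         config.overdispersion))
                inc_counts[s] = inc
                skip_counts[s] = total - inc
            events.append(SplicingEvent(
                event_id=event_id, gene_id=gene_id, ase_type=ase_type,
                regions=regions, inc_counts=inc_counts,
                skip_counts=skip_counts, inc_eff_len=inc_eff,
                skip_eff_len=skip_eff))
            truth_rows.append({
                "event_id": event_id, "ase_type": ase_type,
                "true_psi_control": psi_c, "true_psi_silenced": psi_s,
                "true_dpsi": psi_s - psi_c, "is_diff": is_diff,
                "depth": depth})
    return events, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# region sequences

def make_random_motifs(rng: np.random.Generator, n: int = 10,
                       length_range: tuple[int, int] = (6, 8),
                       sharpness: float = 0.9) -> list[MotifModel]:
    """Random informative PWMs: each position puts ``sharpness`` mass on one
    letter and spreads the rest uniformly."""
    motifs = []
    for m in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        pwm = np.full((L, 4), (1 - sharpness) / 3)
        cons = rng.integers(0, 4, size=L)
        pwm[np.arange(L), cons] = sharpness
        motifs.append(MotifModel(f"M{m:03d}", f"RBP{m:03d}", pwm))
    return motifs


def simulate_region_sequences(events: list[SplicingEvent],
                              motifs: list[MotifModel],
                              config: SimulationConfig,
                              direction_of: dict[str, str] | None = None,
                              planted_motif_ids: list[str] | None = None
                              ) -> tuple[list, pd.DataFrame]:
    """Event-region sequences with planted motif consensus occurrences.

    Background is i.i.d. uniform ACGU.  In regions of events whose
    direction is "up" or "down", each planted motif's consensus is written
    at a Poisson(rate * length/1000) number of uniform offsets.  Returns
    :class:`~spliceshift.motifs.ScanRegion` records plus a truth table of
    every planted occurrence (region id, motif, offset).
    """
    from .motifs import ScanRegion  # local import: motifs must not import us
    if not motifs:
        raise ValueError("motif list must be nonempty")
    config.validate()
    rng = config.rng(3)
    direction_of = direction_of or {}
    planted = [m for m in motifs
               if planted_motif_ids and m.motif_id in planted_motif_ids]
    regions: list[ScanRegion] = []
    truth_rows = []
    letters = np.array(list(RNA_ALPHABET))
    for ev in events:
        pad = config.flank_length_mx if ev.ase_type == "MX" \
            else config.flank_length
        direction = direction_of.get(ev.event_id, "null")
        alt_items = [(k, v) for k, v in sorted(ev.regions.items())
                     if k.startswith("alt")]
        for alt_label, alt in alt_items:
            suffix = "" if len(alt_items) == 1 else f".{alt_label}"
            parts = {
                "upstream_flank": GenomicInterval(
                    alt.chrom, max(0, alt.start - pad), alt.start, alt.strand),
                "spliced_region": alt,
                "downstream_flank": GenomicInterval(
                    alt.chrom, alt.end, alt.end + pad, alt.strand),
            }
            for label, iv in parts.items():
                length = len(iv)
                seq = letters[rng.integers(0, 4, size=length)]
                region_id = f"{ev.event_id}{suffix}|{label}"
                if direction in ("up", "down") and planted:
                    for m in planted:
                        cons = m.consensus()
                        if length < len(cons):
                            continue
                        n_occ = rng.poisson(
                            config.motif_plant_rate * length / 1000.0)
                        for _ in range(n_occ):
                            off = int(rng.integers(0, length - len(cons) + 1))
                            seq[off:off + len(cons)] = list(cons)
                            truth_rows.append({
                                "region_id": region_id,
                                "motif_id": m.motif_id, "offset": off})
                regions.append(ScanRegion(
                    event_id=f"{ev.event_id}{suffix}", ase_type=ev.ase_type,
                    region_label=label, interval=iv,
                    sequence="".join(seq), direction=direction))
    return regions, pd.DataFrame(
        truth_rows, columns=["region_id", "motif_id", "offset"])


# ---------------------------------------------------------------------------
# pseudo-cohort

def simulate_cohort(events: list[SplicingEvent] | list[str],
                    config: SimulationConfig
                    ) -> tuple[list[CohortSample], pd.DataFrame]:
    """Pseudo-cohort with planted PSI-marker correlation and hazards.

    Marker expression (log2 scale) is group-shifted: high in ER+ tumors,
    low in ER- tumors, intermediate in normals.  The first
    ``n_planted_cohort_events`` events carry (a) a Gaussian-copula rank
    correlation of ``planted_rho`` between PSI and marker within each
    group, and (b) a group-level PSI shift of ``planted_group_dpsi`` in
    tumors vs normals/ER-.  The first planted event also multiplies the
    exponential survival hazard by ``planted_hazard_ratio`` for samples
    above its median PSI; censoring is independent uniform.
    """
    config.validate()
    rng = config.rng(4)
    event_ids = [e if isinstance(e, str) else e.event_id for e in events]
    n_planted = min(config.n_planted_cohort_events, len(event_ids))
    planted_ids = event_ids[:n_planted]
    group_mu = {"ERpos_tumor": 12.0, "ERneg_tumor": 7.0, "normal": 10.0}
    group_sd = {"ERpos_tumor": 1.2, "ERneg_tumor": 1.0, "normal": 1.0}
    # bivariate-normal latent correlation giving the target Spearman rho
    r_latent = 2.0 * math.sin(math.pi * config.planted_rho / 6.0)
    conc = 20.0  # beta concentration for PSI noise
    samples: list[CohortSample] = []
    base_mean = {e: rng.uniform(0.2, 0.8) for e in event_ids}
    idx = 0
    for group, n in config.cohort_sizes.items():
        z_marker = rng.standard_normal(n)
        marker = group_mu[group] + group_sd[group] * z_marker
        for i in range(n):
            sid = f"S{idx:04d}"
            idx += 1
            psi = {}
            for e in event_ids:
                if rng.random() < config.psi_missing_rate:
                    continue
                if e in planted_ids:
                    shift = config.planted_group_dpsi \
                        if group == "ERpos_tumor" else 0.0
                    mean = float(np.clip(0.4 + shift, 0.05, 0.95))
                    z2 = r_latent * z_marker[i] + \
                        math.sqrt(1 - r_latent ** 2) * rng.standard_normal()
                    u = norm.cdf(z2)
                    psi[e] = float(beta_dist.ppf(
                        u, mean * conc, (1 - mean) * conc))
                else:
                    m = base_mean[e]
                    psi[e] = float(rng.beta(m * conc, (1 - m) * conc))
            samples.append(CohortSample(
                sample_id=sid, group=group,
                marker_expr=float(marker[i]), psi_by_event=psi))
    # survival driven by the first planted event's median split
    surv_event = planted_ids[0] if planted_ids else None
    if surv_event is not None:
        vals = [s.psi_by_event[surv_event] for s in samples
                if surv_event in s.psi_by_event]
        med = float(np.median(vals)) if vals else 0.5
    for s in samples:
        hr = 1.0
        if surv_event is not None and \
                s.psi_by_event.get(surv_event, med) > med:
            hr = config.planted_hazard_ratio
        for prefix, scale in (("os", 1.0), ("dfs", 1.4)):
            t = rng.exponential(1.0 / (config.baseline_hazard * hr * scale))
            c = rng.uniform(config.censor_low, config.censor_high)
            setattr(s, f"{prefix}_time", float(min(t, c)))
            setattr(s, f"{prefix}_event", bool(t <= c))
    truth = pd.DataFrame([{
        "event_id": e,
        "planted_rho": config.planted_rho if e in planted_ids else 0.0,
        "planted_group_dpsi": (config.planted_group_dpsi
                               if e in planted_ids else 0.0),
        "is_survival_event": e == surv_event,
        "hazard_ratio": (config.planted_hazard_ratio
                         if e == surv_event else 1.0),
    } for e in event_ids])
    return samples, truth
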