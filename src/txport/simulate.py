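"""Synthetic data generators with known planted truth.

Every downstream stage of the package has a generator here that emulates
its input data kind with parameters the analysis should recover:

- AP-MS spectral-count matrices: overdispersed (negative binomial) prey
  counts proportional to per-sample bait recovery, a sticky-contaminant
  layer shared with no-tag controls, and a planted set of fold-changed
  interactors.
- Two-channel tiling-array probe tracks: per-gene 5'->3' occupancy decay
  in log2 space, a smooth intensity-dependent dye-bias curve, and
  lognormal replicate noise.
- qPCR Ct tables consistent with the percent-of-input formula.
- Per-cell FISH retention tallies (Bernoulli per cell).

All randomness flows from one explicit seed through independent spawned
streams; identical (seed, parameters) give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genes import GeneModel, check_non_overlapping
from .matrix import SampleMeta, SpectralCountMatrix
from .qpcr import CtMeasurement
from .tracks import ProbeSignalTrack


@dataclass
class SyntheticTruth:
    """The generative parameters a simulated dataset instantiates."""

    seed: int = 0
    planted_log2fc: Mapping[str, float] = field(default_factory=dict)
    background_rate: float = 1.0
    bait_efficiency: Mapping[str, float] = field(default_factory=dict)
    processivity_delta: Mapping[str, float] = field(default_factory=dict)
    dye_bias_coefs: Sequence[float] = ()
    retention_prob: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValidationError("background_rate must be non-negative")
        for s, e in self.bait_efficiency.items():
            if e <= 0:
                raise ValidationError(
                    f"bait_efficiency for {s!r} must be positive")
        for s, p in self.retention_prob.items():
            if not 0 <= p <= 1:
                raise ValidationError(
                    f"retention_prob for {s!r} must be in [0, 1]")

    def stream(self, label: str) -> np.random.Generator:
        """Independent RNG stream for one simulator, derived from the seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(
            sum(ord(c) for c in label), len(label)))
        return np.random.default_rng(ss)


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float
            ) -> np.ndarray:
    """Negative binomial draws with var = mean + dispersion*mean^2
    (Poisson when dispersion=0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / dispersion
        p = 1.0 / (1.0 + dispersion * mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_apms(design: Sequence[SampleMeta], truth: SyntheticTruth,
                  n_proteins: int, baseline_mean: float = 20.0,
                  bait_mean: float = 300.0, dispersion: float = 0.2,
                  bait_dispersion: float = 0.02,
                  sticky_fraction: float = 0.3, n_duplicates: int = 0,
                  reference_condition: str | None = None
                  ) -> SpectralCountMatrix:
    """Simulate an AP-MS spectral-count matrix.

    Prey generative means are ``baseline x bait_efficiency[sample] x
    2**planted_log2fc`` (the fold change applies in non-reference
    conditions) plus the background rate; no-tag controls see only the
    background, except for a sticky-contaminant fraction of preys that
    appear there at their full tagged-sample mean — these exercise the
    no-tag filters. Counts are negative binomial with the given
    dispersion; the bait row uses ``bait_dispersion``, much tighter than
    the preys, because a bait is recovered consistently by construction
    of the purification and its replicate scatter would otherwise leak
    into every bait-normalized prey. ``n_duplicates`` extra rows with
    ``__dup<k>`` identifiers replicate the first preys to exercise
    duplicate collapse.
    """
    tagged = [s for s in design if not s.is_no_tag]
    if not tagged:
        raise ConfigurationError("design has no tagged samples")
    if not any(s.is_no_tag for s in design):
        raise ConfigurationError("design has no no-tag control")
    baits = {s.bait_protein for s in tagged}
    if None in baits:
        raise ConfigurationError("tagged sample missing a bait")
    if n_proteins < 2:
        raise ValidationError("n_proteins must be >= 2 (bait plus preys)")
    if not 0 <= sticky_fraction <= 1:
        raise ValidationError("sticky_fraction must be in [0, 1]")
    if dispersion < 0:
        raise ValidationError("dispersion must be non-negative")

    ref = reference_condition
    if ref is None:
        ref = tagged[0].condition
    rng = truth.stream("apms")
    n_prey = n_proteins - len(baits)
    prey_ids = [f"P{i:04d}" for i in range(1, n_prey + 1)]
    n_sticky = int(round(sticky_fraction * n_prey))
    sticky = set(rng.permutation(prey_ids)[:n_sticky].tolist())

    rows = list(sorted(baits)) + prey_ids
    dup_of: list[tuple[str, str]] = []
    for k in range(n_duplicates):
        src = prey_ids[k % n_prey]
        dup_id = f"{src}__dup{k + 1}"
        rows.append(dup_id)
        dup_of.append((dup_id, src))
    dup_map = dict(dup_of)

    is_bait_row = np.array([dup_map.get(p, p) in baits for p in rows])
    values = np.zeros((len(rows), len(design)))
    for j, s in enumerate(design):
        eff = truth.bait_efficiency.get(s.sample_id, 1.0)
        means = np.zeros(len(rows))
        for i, pid in enumerate(rows):
            src = dup_map.get(pid, pid)
            if src in baits:
                means[i] = 0.0 if s.is_no_tag else bait_mean * eff
                continue
            if s.is_no_tag:
                # sticky contaminants bind the resin itself: their no-tag
                # mean matches their reference tagged-sample mean
                means[i] = (baseline_mean * eff if src in sticky
                            else truth.background_rate)
            else:
                lfc = truth.planted_log2fc.get(src, 0.0)
                fold = 2.0 ** lfc if s.condition != ref else 1.0
                means[i] = baseline_mean * eff * fold + truth.background_rate
        col = _nbinom(rng, means, dispersion)
        col[is_bait_row] = _nbinom(rng, means[is_bait_row], bait_dispersion)
        values[:, j] = col
    df = pd.DataFrame(values, index=rows,
                      columns=[s.sample_id for s in design])
    return SpectralCountMatrix(values=df, samples=list(design))


def simulate_chip_tracks(genes: Sequence[GeneModel], truth: SyntheticTruth,
                         probe_spacing: int = 60, n_replicates: int = 2,
                         contig_length: int | None = None,
                         gene_level_log2: float = 2.0,
                         baseline_log2: float = 0.0,
                         noise_sd: float = 0.1,
                         abundance_range: tuple[float, float] = (8.0, 14.0),
                         delta_window: int = 300) -> list[ProbeSignalTrack]:
    """Simulate two-channel probe tracks over a synthetic contig.

    The underlying log2 IP/input occupancy is ``baseline_log2`` between
    genes and, within each gene body, ``gene_level_log2`` with a linear
    5'->3' decline anchored so that the mean over the last
    ``delta_window`` bp sits exactly ``processivity_delta[gene]`` log2
    units below the mean over the first ``delta_window`` bp — the planted
    delta is thus, by construction, the quantity the processivity score
    measures. Per probe, a random average intensity A is drawn, the dye-bias
    polynomial (coefficients in ``truth.dye_bias_coefs``, highest power
    first) is evaluated at A and added to the true M together with
    Gaussian log-scale noise, and the pair is folded back into IP/input
    channel intensities (IP = 2**(A + M/2), input = 2**(A - M/2)).
    """
    if probe_spacing < 1:
        raise ValidationError("probe_spacing must be >= 1")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    genes = list(genes)
    check_non_overlapping(genes)
    contigs = {g.contig for g in genes} or {"synthetic_contig"}
    if len(contigs) > 1:
        raise ValidationError("simulator uses a single synthetic contig")
    contig = next(iter(contigs))
    if contig_length is None:
        # default genome: a 500-kb synthetic contig, so enriched gene
        # bodies stay a minority of probes (as on a whole-genome array)
        contig_length = max(500_000,
                            max((g.end for g in genes), default=0) + 5000)
    rng = truth.stream("chip")
    positions = np.arange(0, contig_length, probe_spacing, dtype=np.int64)

    m_true = _underlying_log2(genes, truth, positions, gene_level_log2,
                              baseline_log2, delta_window)

    tracks = []
    for _ in range(n_replicates):
        a = rng.uniform(*abundance_range, size=positions.size)
        bias = (np.polyval(truth.dye_bias_coefs, a)
                if len(truth.dye_bias_coefs) else 0.0)
        m_obs = m_true + bias + (rng.normal(0.0, noise_sd, positions.size)
                                 if noise_sd > 0 else 0.0)
        ip = 2.0 ** (a + m_obs / 2.0)
        inp = 2.0 ** (a - m_obs / 2.0)
        tracks.append(ProbeSignalTrack(contig=contig, positions=positions,
                                       ip=ip, inp=inp))
    return tracks


def _underlying_log2(genes: Sequence[GeneModel], truth: SyntheticTruth,
                     positions: np.ndarray, gene_level_log2: float,
                     baseline_log2: float, delta_window: int) -> np.ndarray:
    positions = np.asarray(positions, dtype=np.int64)
    m = np.full(positions.size, float(baseline_log2))
    for g in genes:
        delta = truth.processivity_delta.get(g.gene_id, 0.0)
        sel = (positions >= g.start) & (positions < g.end)
        p = positions[sel]
        off = (p - g.tss) if g.strand == "+" else (g.tss - 1 - p)
        # ramp anchored on end-window means: the continuous average over
        # [0, w) is gene_level and over [L-w, L) is gene_level - delta
        span = max(g.length - delta_window, 1)
        m[sel] = gene_level_log2 - delta * (off - (delta_window - 1) / 2) / span
    return m


def true_log2_occupancy(genes: Sequence[GeneModel], truth: SyntheticTruth,
                        positions: np.ndarray,
                        gene_level_log2: float = 2.0,
                        baseline_log2: float = 0.0,
                        delta_window: int = 300) -> np.ndarray:
    """Noise-free underlying log2 occupancy at given positions (oracle
    companion to :func:`simulate_chip_tracks`)."""
    return _underlying_log2(genes, truth, positions, gene_level_log2,
                            baseline_log2, delta_window)


def simulate_qpcr(true_percent_input: Mapping[str, float],
                  ct_input_base: float = 20.0, noise_sd: float = 0.1,
                  seed: int = 0, input_fraction: float = 0.01,
                  n_replicates: int = 2) -> list[CtMeasurement]:
    """Simulate qPCR Ct pairs whose percent-of-input equals the given
    truth up to Gaussian cycle noise on the IP Ct."""
    for amp, pi in true_percent_input.items():
        if pi <= 0:
            raise ValidationError(
                f"percent input for {amp!r} must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    c = np.log2(1.0 / input_fraction)
    out = []
    for amp, pi in true_percent_input.items():
        for rep in range(1, n_replicates + 1):
            ct_ip = (ct_input_base - c - np.log2(pi / 100.0)
                     + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            out.append(CtMeasurement(amplicon=amp, ct_input=ct_input_base,
                                     ct_ip=float(ct_ip),
                                     input_fraction=input_fraction,
                                     replicate=rep))
    return out


def simulate_fish(truth: SyntheticTruth, n_cells: Mapping[str, int],
                  seed: int | None = None):
    """Simulate per-strain FISH tallies: each scored cell retains polyA
    RNA in the nucleus independently with the strain's retention
    probability."""
    from .fish import CellTally

    rng = (np.random.default_rng(np.random.SeedSequence(seed))
           if seed is not None else truth.stream("fish"))
    out = []
    for strain, n in n_cells.items():
        if n < 1:
            raise ValidationError(f"n_cells for {strain!r} must be >= 1")
        if strain not in truth.retention_prob:
            raise ConfigurationError(
                f"no retention probability for strain {strain!r}")
        p = truth.retention_prob[strain]
        out.append(CellTally(strain=strain, n_scored=int(n),
                             n_retained=int(rng.binomial(n, p))))
    return out
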