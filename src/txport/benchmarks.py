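"""Self-contained benchmark computations over synthetic data.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage, and returns the summary quantity a reader would check:
null-calibration rates, provenance consistency, parameter-recovery
slopes, residual normalization bias. They back both the validation test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .genes import GeneModel
from .interactome import differential_stats, floor_counts, recipe_preset, \
    run_recipe
from .matrix import SampleMeta, SpectralCountMatrix
from .metagene import chip_processivity
from .simulate import SyntheticTruth, simulate_apms, simulate_chip_tracks
from .tracks import combine_replicates, ma_loess_normalize


def _design(n_reps=3, conditions=("WT", "mut"), bait="BAIT", n_no_tag=1):
    design = []
    for cond in conditions:
        for r in range(1, n_reps + 1):
            design.append(SampleMeta(f"{cond}_{r}", cond, False, bait, r))
    for k in range(1, n_no_tag + 1):
        design.append(SampleMeta(f"no_tag_{k}", "no_tag", True, None, k))
    return design


def null_pvalue_calibration(seed: int, n_matrices: int = 200,
                            n_proteins: int = 51, n_reps: int = 3,
                            dispersion: float = 0.2, alpha: float = 0.1
                            ) -> dict:
    """Fraction of null-protein p-values below ``alpha``.

    Simulates matrices with no planted effects (3 vs 3 replicates,
    negative-binomial counts), floors them, and runs the per-protein
    differential t-test; a calibrated test rejects a fraction ``alpha``
    of the time, within binomial sampling error.
    """
    design = _design(n_reps=n_reps)
    hits = 0
    total = 0
    for i in range(n_matrices):
        truth = SyntheticTruth(seed=seed + i)
        m = simulate_apms(design, truth, n_proteins, dispersion=dispersion,
                          sticky_fraction=0.0)
        stats = differential_stats(floor_counts(m, 0.1), "WT", "mut")
        p = stats.drop(index="BAIT")["p_value"].to_numpy()
        hits += int((p < alpha).sum())
        total += p.size
    sd = float(np.sqrt(alpha * (1 - alpha) / total))
    return {"fraction": hits / total, "n_tests": total,
            "binomial_sd": sd, "alpha": alpha}


def provenance_oracle_agreement(seed: int, n_matrices: int = 50) -> dict:
    """On fuzzed synthetic matrices, compare run_recipe's sequential
    per-step removal sets against isolated re-application of each filter
    plus set arithmetic (filters are row-wise, so the two must agree)."""
    from .interactome import _apply_step

    rng = np.random.default_rng(seed)
    recipe = recipe_preset("rpb1_fcp1")
    design = _design(n_reps=2, conditions=("WT", "fcp1-1"), bait="RPB1")
    agree = 0
    for _ in range(n_matrices):
        truth = SyntheticTruth(seed=int(rng.integers(2**31)),
                               background_rate=float(rng.uniform(0, 3)))
        m = simulate_apms(design, truth, int(rng.integers(10, 60)),
                          baseline_mean=float(rng.uniform(2, 40)),
                          sticky_fraction=float(rng.uniform(0, 0.6)))
        res = run_recipe(m, recipe)
        current = m
        seen: set[str] = set()
        ok = True
        for rec in res.provenance:
            if rec.step in ("floor", "normalize"):
                current, _ = _apply_step(current, rec.step, recipe)
                continue
            staged = current.subset(
                [p for p in current.protein_ids if p not in seen])
            oracle = _apply_step(staged, rec.step, recipe)[1]
            if sorted(set(oracle.removed) - seen) != sorted(rec.removed):
                ok = False
            seen |= set(oracle.removed)
        agree += int(ok)
    return {"n_agree": agree, "n_matrices": n_matrices}


def processivity_recovery(seed: int, n_genes: int = 100,
                          gene_length: int = 2000, noise_sd: float = 0.05,
                          delta_range: tuple[float, float] = (0.0, 2.0)
                          ) -> dict:
    """Regression of recovered processivity scores on planted scores.

    Simulates a gene set with uniform planted 5'->3' decays, runs the
    full normalize -> combine -> score pipeline, and regresses recovered
    on planted (-delta) scores; faithful recovery gives slope ~1.
    """
    rng = np.random.default_rng(seed)
    genes, deltas = [], {}
    pos = 2000
    for i in range(n_genes):
        if i % 2 == 0:
            g = GeneModel(f"g{i}", "chr", "+", pos, pos + gene_length)
        else:
            g = GeneModel(f"g{i}", "chr", "-", pos + gene_length, pos)
        genes.append(g)
        deltas[g.gene_id] = float(rng.uniform(*delta_range))
        pos += gene_length + 3000
    truth = SyntheticTruth(seed=seed, processivity_delta=deltas)
    tracks = simulate_chip_tracks(genes, truth, noise_sd=noise_sd,
                                  contig_length=pos + 2000)
    combined = combine_replicates([ma_loess_normalize(t) for t in tracks])
    recovered = np.array([chip_processivity(g, combined).score
                          for g in genes])
    planted = np.array([-deltas[g.gene_id] for g in genes])
    slope, intercept = np.polyfit(planted, recovered, 1)
    return {"slope": float(slope), "intercept": float(intercept),
            "n_genes": n_genes}


def loess_bias_removal(seed: int, n_probes: int = 2000,
                       coefs: tuple[float, ...] = (0.02, -0.66, 7.56, -29.92)
                       ) -> dict:
    """Residual per-A-decile mean M after normalizing away a planted
    monotone dye-bias polynomial at zero noise.

    The default coefficients are 0.3(A-11) + 0.02(A-11)^3 expanded in raw
    A: a monotone curve spanning about +-1.4 log2 units over the
    simulated intensity range.
    """
    genes: list[GeneModel] = []
    truth = SyntheticTruth(seed=seed, dye_bias_coefs=coefs)
    track = simulate_chip_tracks(genes, truth, probe_spacing=60,
                                 n_replicates=1, noise_sd=0.0,
                                 contig_length=n_probes * 60)[0]
    out = ma_loess_normalize(track)
    _, a = track.ma_values()
    deciles = np.quantile(a, np.linspace(0, 1, 11))
    per_decile = []
    for lo, hi in zip(deciles[:-1], deciles[1:]):
        sel = (a >= lo) & (a <= hi)
        per_decile.append(float(out.log2_ratio[sel].mean()))
    return {"max_abs_decile_bias": float(np.max(np.abs(per_decile))),
            "n_probes": n_probes}
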