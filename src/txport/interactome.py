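"""Differential interactome analysis of AP-MS spectral counts.

Implements the spectral-count processing recipes used for bait
purifications compared against no-tag controls: flooring, bait
normalization, contaminant and low-abundance filtering, enrichment gating,
duplicate-ID collapse, log2 relative abundance with average intensity, a
per-protein t-test, and volcano-style up/down/ns calls.

Three named presets reproduce the published workflows:

``rpb1_fcp1``
    RNAPII (Rpb1-TAP) purified from WT and *fcp1-1* cells, 2+2 replicates.
    Counts are floored to 0.1 and normalized to the bait level; proteins
    averaging >10 spectral counts in no-tag controls, or <5 in both
    conditions, are removed; log2(fcp1-1/WT) and average intensity are
    reported and twofold changes called (no p-value gate).

``ubp15_tap``
    Single Ubp15-TAP purification vs a no-tag control. Proteins with >10
    no-tag counts, <2-fold tag/no-tag enrichment, or <5 counts in the
    tagged sample are removed, then duplicate IDs collapsed.

``mex67_ubp15``
    Mex67-3Flag purified from WT and *ubp15Δ*, 3+3 replicates. Proteins
    failing the 5-fold-over-no-tag or average-of-8 gates are removed, the
    between-condition bait ratio is normalized to exactly 1, and twofold
    changes with t-test p < 0.1 are called.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComputationError, ConfigurationError, ValidationError
from .matrix import SpectralCountMatrix

BaitMode = Literal["per_sample_bait", "cross_condition_bait_ratio", "none"]
GateLogic = Literal["fail_either", "fail_both"]

_DUP_SUFFIX = re.compile(r"__dup\d+$")


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------

def floor_counts(m: SpectralCountMatrix, floor_value: float = 0.1
                 ) -> SpectralCountMatrix:
    """Replace every count below ``floor_value`` by ``floor_value``.

    Flooring keeps subsequent log-ratios finite for proteins absent from
    one sample. Idempotent.
    """
    if not np.isfinite(floor_value) or floor_value <= 0:
        raise ValidationError(f"floor_value must be positive, got {floor_value}")
    return m.with_values(m.values.clip(lower=floor_value))


def normalize_to_bait(m: SpectralCountMatrix, mode: BaitMode,
                      reference_condition: str | None = None
                      ) -> SpectralCountMatrix:
    """Rescale tagged samples so bait recovery is comparable.

    ``per_sample_bait`` rescales each tagged sample so its bait count
    equals the cross-sample mean bait count (sample-level recovery
    correction). ``cross_condition_bait_ratio`` rescales the non-reference
    condition by (mean bait in reference)/(mean bait in other) so the
    between-condition bait ratio is exactly 1. No-tag controls are never
    rescaled.
    """
    if mode == "none":
        return m
    values = m.values.copy()
    tagged = [s for s in m.samples if not s.is_no_tag]
    if not tagged:
        raise ConfigurationError("bait normalization requires tagged samples")
    baits = {}
    for s in tagged:
        b = values.at[s.bait_protein, s.sample_id]
        if b <= 0:
            raise ComputationError(
                f"bait {s.bait_protein!r} is zero in sample {s.sample_id!r}; "
                "floor counts before normalizing"
            )
        baits[s.sample_id] = float(b)

    if mode == "per_sample_bait":
        target = float(np.mean(list(baits.values())))
        for sid, b in baits.items():
            values[sid] = values[sid] * (target / b)
    elif mode == "cross_condition_bait_ratio":
        conds = m.tagged_conditions
        if len(conds) != 2:
            raise ConfigurationError(
                "cross_condition_bait_ratio needs exactly two tagged "
                f"conditions, found {conds}"
            )
        ref = reference_condition if reference_condition is not None else conds[0]
        if ref not in conds:
            raise ConfigurationError(f"unknown reference condition {ref!r}")
        other = conds[0] if conds[1] == ref else conds[1]
        mean_ref = float(np.mean([baits[s] for s in m.sample_ids(
            tagged=True, condition=ref)]))
        mean_other = float(np.mean([baits[s] for s in m.sample_ids(
            tagged=True, condition=other)]))
        scale = mean_ref / mean_other
        for sid in m.sample_ids(tagged=True, condition=other):
            values[sid] = values[sid] * scale
    else:
        raise ConfigurationError(f"unknown bait normalization mode {mode!r}")
    return m.with_values(values)


def filter_no_tag(m: SpectralCountMatrix, no_tag_max_avg: float = 10.0
                  ) -> tuple[SpectralCountMatrix, list[str]]:
    """Remove proteins averaging strictly more than ``no_tag_max_avg``
    spectral counts in the no-tag controls (nonspecific background)."""
    no_tag = m.require_no_tag()
    means = m.mean_over(no_tag)
    removed = list(means.index[means > no_tag_max_avg])
    return m.subset(means.index[means <= no_tag_max_avg]), removed


def filter_low_abundance(m: SpectralCountMatrix, min_condition_avg: float,
                         conditions: Sequence[str]
                         ) -> tuple[SpectralCountMatrix, list[str]]:
    """Remove proteins whose mean tagged count is strictly below
    ``min_condition_avg`` in *every* listed condition."""
    if not conditions:
        raise ConfigurationError("at least one condition required")
    below = None
    for cond in conditions:
        ids = m.require_condition(cond)
        b = m.mean_over(ids) < min_condition_avg
        below = b if below is None else (below & b)
    removed = list(below.index[below])
    return m.subset(below.index[~below]), removed


def filter_enrichment(m: SpectralCountMatrix,
                      min_fold_over_notag: float | None,
                      min_tagged_avg: float | None,
                      logic: GateLogic = "fail_either",
                      notag_floor: float = 0.1
                      ) -> tuple[SpectralCountMatrix, list[str]]:
    """Remove proteins insufficiently enriched over the no-tag background.

    Fold enrichment is (mean over tagged samples) / (mean over no-tag
    samples, floored at ``notag_floor`` to avoid division by zero). Under
    ``fail_either`` a protein is removed when it fails *any* active gate
    (it must pass both to stay); under ``fail_both`` only when it fails
    all active gates.
    """
    if min_fold_over_notag is None and min_tagged_avg is None:
        return m, []
    tagged_mean = m.mean_over(m.sample_ids(tagged=True))
    fails = []
    if min_fold_over_notag is not None:
        if min_fold_over_notag <= 0:
            raise ValidationError("min_fold_over_notag must be positive")
        notag_mean = m.mean_over(m.require_no_tag()).clip(lower=notag_floor)
        fails.append((tagged_mean / notag_mean) < min_fold_over_notag)
    if min_tagged_avg is not None:
        if min_tagged_avg <= 0:
            raise ValidationError("min_tagged_avg must be positive")
        fails.append(tagged_mean < min_tagged_avg)
    if logic == "fail_either":
        fail = fails[0]
        for f in fails[1:]:
            fail = fail | f
    elif logic == "fail_both":
        fail = fails[0]
        for f in fails[1:]:
            fail = fail & f
    else:
        raise ConfigurationError(f"unknown enrichment gate logic {logic!r}")
    removed = list(fail.index[fail])
    return m.subset(fail.index[~fail]), removed


def canonical_protein_id(protein_id: str) -> str:
    """Default canonicalization: strip a trailing ``__dup<k>`` suffix."""
    return _DUP_SUFFIX.sub("", protein_id)


def collapse_duplicates(m: SpectralCountMatrix,
                        id_map: Mapping[str, str] | None = None
                        ) -> tuple[SpectralCountMatrix, list[str]]:
    """Collapse rows whose IDs refer to the same protein.

    ``id_map`` maps redundant IDs to canonical ones; without it, IDs are
    canonicalized by :func:`canonical_protein_id`. Of each duplicate group
    the row with the highest total count is kept (ties broken by the
    lexicographically smallest ID); the discarded IDs are returned.
    """
    canon = pd.Series(
        [id_map.get(p, p) if id_map else canonical_protein_id(p)
         for p in m.values.index],
        index=m.values.index,
    )
    totals = m.values.sum(axis=1)
    keep: dict[str, str] = {}
    for pid in m.values.index:
        c = canon[pid]
        best = keep.get(c)
        if best is None or (totals[pid], ) > (totals[best], ) or (
                totals[pid] == totals[best] and pid < best):
            keep[c] = pid
    kept_rows = set(keep.values())
    collapsed = [p for p in m.values.index if p not in kept_rows]
    out = m.values.loc[[p for p in m.values.index if p in kept_rows]].copy()
    out.index = [canon[p] for p in out.index]
    return m.with_values(out), collapsed


# ---------------------------------------------------------------------------
# statistics and calls
# ---------------------------------------------------------------------------

def two_sample_ttest(a: np.ndarray, b: np.ndarray, var_floor: float = 1e-12,
                     equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value with degenerate-data handling.

    Defaults to the pooled-variance (Student) test: with the equal group
    sizes typical of these designs the pooled and Welch statistics
    coincide, and at n=3 the pooled degrees of freedom keep the test
    calibrated where Welch's Satterthwaite df makes it conservative.
    ``equal_var=False`` selects Welch. With n=3 replicates of floored
    counts both groups can have zero variance; equal means then return
    p=1, otherwise both variances are floored at ``var_floor``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return float("nan")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= var_floor and vb <= var_floor:
        if np.isclose(a.mean(), b.mean()):
            return 1.0
        va = max(va, var_floor)
        vb = max(vb, var_floor)
        sa, sb = va / a.size, vb / b.size
        t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
        return float(2 * sps.t.sf(abs(t), df))
    with warnings.catch_warnings():
        # scipy warns on near-constant groups; the degenerate exact-zero
        # case is handled above and near-zero variance is legitimate here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def differential_stats(m: SpectralCountMatrix, cond_a: str, cond_b: str,
                       equal_var: bool = True) -> pd.DataFrame:
    """Per-protein log2 ratio, average intensity, and t-test p-value.

    ``log2_ratio`` is log2(mean_B / mean_A) of the (floored, normalized)
    counts; ``avg_intensity`` is the mean over all tagged samples;
    ``p_value`` comes from a two-sided two-sample t-test on per-replicate
    counts (NaN when either condition has fewer than two replicates).
    """
    ids_a = m.require_condition(cond_a)
    ids_b = m.require_condition(cond_b)
    mean_a = m.mean_over(ids_a)
    mean_b = m.mean_over(ids_b)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ComputationError("zero condition means; floor counts first")
    log2_ratio = np.log2(mean_b / mean_a)
    avg_intensity = m.mean_over(m.sample_ids(tagged=True))
    if len(ids_a) >= 2 and len(ids_b) >= 2:
        av = m.values[ids_a].to_numpy()
        bv = m.values[ids_b].to_numpy()
        p = np.array([two_sample_ttest(av[i], bv[i], equal_var=equal_var)
                      for i in range(av.shape[0])])
    else:
        p = np.full(m.n_proteins, np.nan)
    return pd.DataFrame(
        {"log2_ratio": log2_ratio, "avg_intensity": avg_intensity,
         "p_value": p},
        index=m.values.index,
    )


def classify_hits(stats: pd.DataFrame, fc_call_threshold: float = 2.0,
                  p_call_threshold: float | None = None) -> pd.Series:
    """Volcano classification: ``up``/``down`` for at-least-``fc``-fold
    changes (|log2 ratio| >= log2 fc, inclusive), gated on p-value when a
    threshold is given; ``ns`` otherwise."""
    if fc_call_threshold <= 0:
        raise ValidationError("fc_call_threshold must be positive")
    lfc = np.log2(fc_call_threshold)
    passes_fc_up = stats["log2_ratio"] >= lfc
    passes_fc_down = stats["log2_ratio"] <= -lfc
    if p_call_threshold is not None:
        sig = stats["p_value"] < p_call_threshold
        passes_fc_up &= sig
        passes_fc_down &= sig
    call = pd.Series("ns", index=stats.index, dtype=object)
    call[passes_fc_up] = "up"
    call[passes_fc_down] = "down"
    return call


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

#: ordered step names understood by :func:`run_recipe`
Step = Literal["floor", "normalize", "filter_no_tag", "filter_low_abundance",
               "filter_enrichment", "collapse_duplicates", "stats"]


@dataclass(frozen=True)
class PurificationRecipe:
    """Ordered, parameterized filter/normalization pipeline for one AP-MS
    comparison. Use :func:`recipe_preset` for the named workflows."""

    name: str
    steps: tuple[str, ...]
    conditions: tuple[str, ...]  # 1 (single purification) or 2 (A then B)
    floor_value: float = 0.1
    bait_normalization_mode: BaitMode = "none"
    reference_condition: str | None = None
    no_tag_max_avg: float = 10.0
    min_condition_avg: float = 5.0
    min_fold_over_notag: float | None = None
    min_tagged_avg: float | None = None
    enrichment_gate_logic: GateLogic = "fail_either"
    fc_call_threshold: float = 2.0
    p_call_threshold: float | None = None
    equal_var_ttest: bool = True
    id_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.floor_value <= 0:
            raise ValidationError("floor_value must be positive")
        if not 1 <= len(self.conditions) <= 2:
            raise ConfigurationError("recipes take one or two conditions")


_FILTER_STEPS = ("filter_no_tag", "filter_low_abundance",
                 "filter_enrichment", "collapse_duplicates")


def recipe_preset(name: str, **overrides) -> PurificationRecipe:
    """Named preset recipes; keyword overrides replace individual fields."""
    presets = {
        "rpb1_fcp1": PurificationRecipe(
            name="rpb1_fcp1",
            steps=("floor", "normalize", "filter_no_tag",
                   "filter_low_abundance", "stats"),
            conditions=("WT", "fcp1-1"),
            bait_normalization_mode="per_sample_bait",
            no_tag_max_avg=10.0,
            min_condition_avg=5.0,
            fc_call_threshold=2.0,
            p_call_threshold=None,
        ),
        "ubp15_tap": PurificationRecipe(
            name="ubp15_tap",
            steps=("filter_no_tag", "filter_enrichment",
                   "filter_low_abundance", "collapse_duplicates"),
            conditions=("WT",),
            no_tag_max_avg=10.0,
            min_fold_over_notag=2.0,
            min_tagged_avg=None,
            min_condition_avg=5.0,
        ),
        "mex67_ubp15": PurificationRecipe(
            name="mex67_ubp15",
            steps=("filter_enrichment", "floor", "normalize", "stats"),
            conditions=("WT", "ubp15D"),
            bait_normalization_mode="cross_condition_bait_ratio",
            reference_condition="WT",
            min_fold_over_notag=5.0,
            min_tagged_avg=8.0,
            fc_call_threshold=2.0,
            p_call_threshold=0.1,
        ),
    }
    if name not in presets:
        raise ConfigurationError(
            f"unknown recipe {name!r}; choose from {sorted(presets)}")
    base = presets[name]
    return replace(base, **overrides) if overrides else base


@dataclass
class ProvenanceRecord:
    step: str
    parameters: dict
    n_removed: int
    removed: list[str]


@dataclass
class InteractomeResult:
    """Per-protein results plus per-step provenance.

    ``table`` has one row per input protein: retained proteins carry
    log2_ratio / avg_intensity / p_value / call, removed proteins carry
    the name of the step that removed them in ``filter_flags``.
    """

    table: pd.DataFrame
    provenance: list[ProvenanceRecord]
    recipe: PurificationRecipe
    n_input: int
    n_retained: int

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": r.step, "n_removed": r.n_removed,
              "parameters": ";".join(f"{k}={v}" for k, v in r.parameters.items())}
             for r in self.provenance]
        )


def _apply_step(m: SpectralCountMatrix, step: str, r: PurificationRecipe
                ) -> tuple[SpectralCountMatrix, ProvenanceRecord | None]:
    if step == "floor":
        return floor_counts(m, r.floor_value), ProvenanceRecord(
            "floor", {"floor_value": r.floor_value}, 0, [])
    if step == "normalize":
        return normalize_to_bait(
            m, r.bait_normalization_mode, r.reference_condition
        ), ProvenanceRecord(
            "normalize", {"mode": r.bait_normalization_mode}, 0, [])
    if step == "filter_no_tag":
        m2, rem = filter_no_tag(m, r.no_tag_max_avg)
        return m2, ProvenanceRecord(
            "filter_no_tag", {"no_tag_max_avg": r.no_tag_max_avg},
            len(rem), rem)
    if step == "filter_low_abundance":
        m2, rem = filter_low_abundance(m, r.min_condition_avg, r.conditions)
        return m2, ProvenanceRecord(
            "filter_low_abundance",
            {"min_condition_avg": r.min_condition_avg,
             "conditions": ",".join(r.conditions)}, len(rem), rem)
    if step == "filter_enrichment":
        m2, rem = filter_enrichment(
            m, r.min_fold_over_notag, r.min_tagged_avg,
            r.enrichment_gate_logic)
        return m2, ProvenanceRecord(
            "filter_enrichment",
            {"min_fold_over_notag": r.min_fold_over_notag,
             "min_tagged_avg": r.min_tagged_avg,
             "logic": r.enrichment_gate_logic}, len(rem), rem)
    if step == "collapse_duplicates":
        m2, rem = collapse_duplicates(m, r.id_map)
        return m2, ProvenanceRecord("collapse_duplicates", {}, len(rem), rem)
    raise ConfigurationError(f"unknown recipe step {step!r}")


def run_recipe(m: SpectralCountMatrix, recipe: PurificationRecipe
               ) -> InteractomeResult:
    """Apply a recipe's steps in order and assemble the result table.

    Every input protein appears exactly once in the output: either
    retained with statistics or flagged with the step that removed it.
    The bait is retained but never called differential (its ratio is
    pinned by normalization).
    """
    n_input = m.n_proteins
    input_ids = m.protein_ids
    provenance: list[ProvenanceRecord] = []
    flags: dict[str, str] = {}
    current = m
    stats_df: pd.DataFrame | None = None
    for step in recipe.steps:
        if step == "stats":
            if len(recipe.conditions) != 2:
                raise ConfigurationError(
                    "stats step requires a two-condition recipe")
            stats_df = differential_stats(
                current, recipe.conditions[0], recipe.conditions[1],
                equal_var=recipe.equal_var_ttest)
            continue
        current, rec = _apply_step(current, step, recipe)
        if rec is not None:
            provenance.append(rec)
            for pid in rec.removed:
                flags.setdefault(pid, rec.step)

    baits = set(current.bait_proteins)
    if stats_df is not None:
        call = classify_hits(stats_df, recipe.fc_call_threshold,
                             recipe.p_call_threshold)
        call[call.index.isin(baits)] = "ns"
        table = stats_df.copy()
        table["call"] = call
    else:
        table = pd.DataFrame(
            {"log2_ratio": np.nan,
             "avg_intensity": current.mean_over(
                 current.sample_ids(tagged=True)),
             "p_value": np.nan, "call": "ns"},
            index=current.values.index)
    table["filter_flags"] = ""
    table["is_bait"] = table.index.isin(baits)

    removed_rows = pd.DataFrame(
        {"log2_ratio": np.nan, "avg_intensity": np.nan, "p_value": np.nan,
         "call": "removed",
         "filter_flags": [flags[p] for p in flags],
         "is_bait": False},
        index=list(flags),
    )
    # preserve input order where possible; collapsed canonical ids keep the
    # surviving row's position
    full = pd.concat([table, removed_rows])
    order = [p for p in input_ids if p in full.index]
    order += [p for p in full.index if p not in set(order)]
    full = full.loc[order]
    return InteractomeResult(
        table=full, provenance=provenance, recipe=recipe,
        n_input=n_input, n_retained=current.n_proteins)
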