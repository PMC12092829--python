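"""Per-class IoU scoring and stage-stratified cross-validation plans.

IoU for class c is |pred==c AND truth==c| / |pred==c OR truth==c|.  When a
class is absent from both prediction and truth the union is empty and the
entry is *undefined* — flagged as NaN and excluded from averages, never
counted as zero.

The split plan mirrors the published cross-validation design: each case
holds out one validation cell per division stage, validation cells are
disjoint across cases, and everything else trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sbfseg.volumes import CLASS_MAP, LabelVolume, N_CLASSES


def iou(pred: LabelVolume, truth: LabelVolume, class_id: int) -> float:
    """IoU of one class; NaN (undefined) when the union is empty."""
    if class_id not in CLASS_MAP:
        raise ValueError(f"class_id must be in 0..{N_CLASSES - 1}, got {class_id}")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.data == class_id
    t = truth.data == class_id
    union = int(np.count_nonzero(p | t))
    if union == 0:
        return float("nan")
    return float(np.count_nonzero(p & t) / union)


def evaluate_volume(pred: LabelVolume, truth: LabelVolume) -> pd.Series:
    """IoU for all six classes of one cell; absent classes are NaN."""
    return pd.Series(
        {CLASS_MAP[c]: iou(pred, truth, c) for c in range(N_CLASSES)},
        name="iou",
    )


def mean_defined(values: pd.Series | pd.DataFrame) -> float:
    """Average over defined entries only (NaN never counted as 0)."""
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def metrics_table(rows: dict[int, pd.Series]) -> pd.DataFrame:
    """Class x stage IoU table plus per-class macro averages over stages."""
    df = pd.DataFrame({f"stage{s}": r for s, r in sorted(rows.items())})
    df["mean"] = df.apply(lambda r: mean_defined(r), axis=1)
    return df


@dataclass(frozen=True)
class SplitCase:
    """One cross-validation case: 5 validation cells, rest training."""

    validation: tuple[str, ...]  # cell ids, one per stage 1..5
    training: tuple[str, ...]


@dataclass(frozen=True)
class SplitPlan:
    cases: tuple[SplitCase, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        seen: set[str] = set()
        for i, case in enumerate(self.cases):
            v = set(case.validation)
            if v & seen:
                raise ValueError(
                    f"case {i} reuses validation cells {sorted(v & seen)}"
                )
            if v & set(case.training):
                raise ValueError(f"case {i} leaks validation cells into training")
            seen |= v


def make_split_plan(
    cells: list[tuple[str, int]],
    n_cases: int,
    seed: int = 0,
    strict: bool = True,
) -> SplitPlan:
    """Stage-stratified plan: per case, one validation cell per stage.

    Deterministic given ``seed``.  Each stage must have at least
    ``n_cases`` cells so validation cells never overlap between cases.
    With ``strict=False`` a stage pool equal to ``n_cases`` (leaving no
    training cell for that stage) is tolerated with a warning instead of
    an error.
    """
    import warnings

    by_stage: dict[int, list[str]] = {s: [] for s in (1, 2, 3, 4, 5)}
    for cell_id, stage in cells:
        if stage not in by_stage:
            raise ValueError(f"stage must be in 1..5, got {stage} for {cell_id}")
        by_stage[stage].append(cell_id)

    rng = np.random.default_rng(seed)
    shuffled: dict[int, list[str]] = {}
    for s, pool in by_stage.items():
        if len(pool) < n_cases:
            raise ValueError(
                f"stage {s} has {len(pool)} cells but {n_cases} cases need "
                f"{n_cases} disjoint validation cells"
            )
        if len(pool) == 1:
            # the lone cell is someone's validation cell, leaving no
            # training cell of that stage for that case
            msg = (f"stage {s} has a single cell: its case will have "
                   "no training cell of that stage")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        idx = rng.permutation(len(pool))
        shuffled[s] = [pool[i] for i in idx]

    all_ids = [cid for cid, _ in cells]
    cases = []
    for i in range(n_cases):
        validation = tuple(shuffled[s][i] for s in (1, 2, 3, 4, 5))
        held = set(validation)
        training = tuple(cid for cid in all_ids if cid not in held)
        cases.append(SplitCase(validation=validation, training=training))
    plan = SplitPlan(cases=tuple(cases))
    plan.validate()
    return plan
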