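"""Stacking individually specific biomarker tests into a screening panel.

Each accepted biomarker is a high-specificity, low-sensitivity test. The
panel rule declares a participant positive when *any* member biomarker is
positive, so adding members can only raise sensitivity and lower
specificity. The optimizer selects members greedily — each step adds the
biomarker giving the largest sensitivity gain whose inclusion keeps panel
specificity at or above a floor (default 0.90) — and records a selection
trace. An exhaustive mode over all subsets is available for small
candidate sets and is used in tests to quantify the greedy gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import BiomarkerProfile, _case_indicator


@dataclass
class PanelModel:
    """Ordered panel members with training performance and the greedy trace."""

    biomarkers: list[str]
    sensitivity: float
    specificity: float
    min_specificity: float
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps({
            "biomarkers": self.biomarkers,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "min_specificity": self.min_specificity,
        }, indent=1))


def evaluate_panel(biomarkers: list[str] | PanelModel, profile: BiomarkerProfile,
                   labels) -> tuple[float, float]:
    """(sensitivity, specificity) of the any-positive rule for a member set.

    An empty panel is (0, 1) by convention."""
    ids = biomarkers.biomarkers if isinstance(biomarkers, PanelModel) else list(biomarkers)
    y = _case_indicator(np.asarray(labels))
    if not ids:
        return 0.0, 1.0
    pos = (profile.matrix[ids].sum(axis=1) > 0).to_numpy(dtype=bool)
    sens = float((pos & y).sum() / max(int(y.sum()), 1))
    spec = float((~pos[~y]).sum() / max(int((~y).sum()), 1))
    return sens, spec


def optimize_panel(
    profile: BiomarkerProfile, labels, min_specificity: float = 0.90,
    method: str = "greedy",
) -> PanelModel:
    """Select a panel maximizing sensitivity subject to a specificity floor.

    ``greedy`` (default): forward selection; each step adds the candidate
    with the largest resulting panel sensitivity among those keeping
    specificity ≥ the floor, breaking ties toward higher resulting
    specificity, then the earliest candidate; stops when no admissible
    candidate adds sensitivity. ``exhaustive`` searches all subsets
    (candidate sets of ≤ 20 only).
    """
    y = _case_indicator(np.asarray(labels))
    cols = list(profile.matrix.columns)
    X = profile.matrix.to_numpy(dtype=bool)
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need both cases and controls")

    if method == "exhaustive":
        return _exhaustive_panel(X, y, cols, min_specificity)
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")

    current = np.zeros(X.shape[0], dtype=bool)
    selected: list[int] = []
    remaining = list(range(len(cols)))
    cur_sens = 0.0
    trace_rows = []
    while remaining:
        best = None  # (sens, spec, -pos) for max()
        best_j = None
        for j in remaining:
            u = current | X[:, j]
            sens = float((u & y).sum() / n_case)
            spec = float((~u[~y]).sum() / n_ctrl)
            if spec < min_specificity - 1e-12 or sens <= cur_sens + 1e-12:
                continue
            key = (sens, spec, -j)
            if best is None or key > best:
                best, best_j = key, j
        if best_j is None:
            break
        current |= X[:, best_j]
        selected.append(best_j)
        remaining.remove(best_j)
        cur_sens = best[0]
        trace_rows.append({"step": len(selected), "biomarker": cols[best_j],
                           "sensitivity": best[0], "specificity": best[1]})
    sens = float((current & y).sum() / n_case) if selected else 0.0
    spec = float((~current[~y]).sum() / n_ctrl) if selected else 1.0
    return PanelModel(
        biomarkers=[cols[j] for j in selected],
        sensitivity=sens, specificity=spec,
        min_specificity=min_specificity,
        trace=pd.DataFrame(trace_rows),
    )


def _exhaustive_panel(X: np.ndarray, y: np.ndarray, cols: list[str],
                      min_specificity: float) -> PanelModel:
    b = X.shape[1]
    if b > 20:
        raise ValueError("exhaustive search limited to 20 candidates")
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    # bitmask of positive cases / positive controls per biomarker
    case_mask = [int.from_bytes(np.packbits(X[y, j]).tobytes(), "big") for j in range(b)]
    ctrl_mask = [int.from_bytes(np.packbits(X[~y, j]).tobytes(), "big") for j in range(b)]
    best = (0.0, 1.0, ())  # sens, spec, members
    union_case = [0] * (1 << b)
    union_ctrl = [0] * (1 << b)
    for s in range(1, 1 << b):
        low = s & -s
        j = low.bit_length() - 1
        union_case[s] = union_case[s ^ low] | case_mask[j]
        union_ctrl[s] = union_ctrl[s ^ low] | ctrl_mask[j]
        spec = 1.0 - union_ctrl[s].bit_count() / n_ctrl
        if spec < min_specificity - 1e-12:
            continue
        sens = union_case[s].bit_count() / n_case
        if (sens, spec) > best[:2]:
            best = (sens, spec, tuple(j for j in range(b) if s >> j & 1))
    members = [cols[j] for j in best[2]]
    return PanelModel(biomarkers=members, sensitivity=best[0],
                      specificity=best[1] if members else 1.0,
                      min_specificity=min_specificity,
                      trace=pd.DataFrame())
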