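"""Longitudinal panel container and CSV I/O.

A panel holds N persons measured on a fixed time grid t_0..t_K.  Variables
are tagged with roles: one outcome (Y), one continuous treatment (A), and
zero or more time-varying confounders (L).  Within a wave the causal
ordering is confounders, then treatment, then the next wave's confounders
(L_0, A_0, L_1, A_1, ..., L_K); the outcome is measured concurrently with
the confounders.  Missing cells are carried as NaN and flagged, never
imputed here.

Variables need not be measured at every wave (e.g. the treatment is often
not recorded at the final wave); the per-variable wave set is part of the
panel's layout and is respected by every downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PanelData",
    "PanelReport",
    "read_panel",
    "write_panel",
    "validate_panel",
    "write_scores",
    "read_scores",
]


@dataclass
class PanelData:
    """Persons x time-grid x role-tagged variables with a missingness mask."""

    person_ids: np.ndarray
    roles: dict
    values: dict[str, np.ndarray]  # name -> (N, K+1), NaN = missing/unmeasured
    waves: dict[str, list[int]]  # name -> wave indices measured by design
    K: int

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("panel needs K >= 2 (three or more time points)")
        n = len(self.person_ids)
        for name, mat in self.values.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, self.K + 1):
                raise ValueError(
                    f"variable {name!r}: expected shape {(n, self.K + 1)}, "
                    f"got {mat.shape} (non-rectangular time grid?)"
                )
            self.values[name] = mat
        for name in self.variable_names:
            if name not in self.values:
                raise ValueError(f"role names unknown variable {name!r}")
        # drop persons with every cell missing: they contribute nothing
        observed = np.zeros(n, dtype=int)
        for mat in self.values.values():
            observed += np.isfinite(mat).sum(axis=1)
        if (observed == 0).any():
            n_drop = int((observed == 0).sum())
            warnings.warn(
                f"dropping {n_drop} person(s) with no observed cells",
                stacklevel=2,
            )
            keep = observed > 0
            self.person_ids = self.person_ids[keep]
            self.values = {k: v[keep] for k, v in self.values.items()}

    # -- layout -----------------------------------------------------------
    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def variable_names(self) -> list[str]:
        """Variable-major ordering: outcome, treatment, then confounders."""
        return [
            self.roles["outcome"],
            self.roles["treatment"],
            *self.roles.get("confounders", []),
        ]

    def missing_mask(self, name: str) -> np.ndarray:
        mask = np.isnan(self.values[name])
        mask[:, [k for k in range(self.K + 1) if k not in self.waves[name]]] = False
        return mask

    def stacked_layout(self) -> list[tuple[str, int]]:
        """(variable, wave) pairs in variable-major, time-ascending order."""
        return [(v, k) for v in self.variable_names for k in self.waves[v]]

    def stacked_matrix(self) -> np.ndarray:
        """Persons x stacked-coordinates matrix (NaN for missing cells)."""
        cols = [self.values[v][:, k] for v, k in self.stacked_layout()]
        return np.column_stack(cols)

    def variable_matrix(self, name: str) -> np.ndarray:
        """Persons x measured-waves matrix for one variable."""
        return self.values[name][:, self.waves[name]]


def _default_waves(values: dict[str, np.ndarray], K: int) -> dict[str, list[int]]:
    waves = {}
    for name, mat in values.items():
        n_cols = min(np.asarray(mat).shape[1], K + 1)
        measured = [k for k in range(n_cols) if np.isfinite(mat[:, k]).any()]
        waves[name] = measured if measured else list(range(n_cols))
    return waves


def make_panel(
    person_ids,
    roles: dict,
    values: dict[str, np.ndarray],
    K: int,
    waves: dict[str, list[int]] | None = None,
) -> PanelData:
    if waves is None:
        waves = _default_waves(values, K)
    return PanelData(
        person_ids=np.asarray(person_ids),
        roles=roles,
        values=dict(values),
        waves=waves,
        K=K,
    )


# -- CSV I/O ---------------------------------------------------------------

def read_panel(
    path,
    schema: dict,
    layout: str = "long",
    sep: str = "_",
) -> PanelData:
    """Read a panel from CSV.

    ``schema`` maps roles to variable names: ``{"outcome": "Y", "treatment":
    "A", "confounders": ["L"]}``.  Long layout expects columns (person,
    time, variable, value); wide layout expects ``<variable><sep><time>``
    columns plus a ``person`` column.
    """
    if "outcome" not in schema or "treatment" not in schema:
        raise ValueError("schema must name one outcome and one treatment")
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"no records in {path}")
    names = [schema["outcome"], schema["treatment"], *schema.get("confounders", [])]

    if layout == "long":
        required = {"person", "time", "variable", "value"}
        if not required.issubset(frame.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        unknown = set(frame["variable"].unique()) - set(names)
        if unknown:
            raise ValueError(f"unknown variables in file: {sorted(unknown)}")
        K = int(frame["time"].max())
        persons = np.asarray(sorted(frame["person"].unique()))
        index = {p: i for i, p in enumerate(persons)}
        values = {name: np.full((len(persons), K + 1), np.nan) for name in names}
        for row in frame.itertuples(index=False):
            values[row.variable][index[row.person], int(row.time)] = row.value
    elif layout == "wide":
        if "person" not in frame.columns:
            raise ValueError("wide layout needs a 'person' column")
        persons = frame["person"].to_numpy()
        parsed = []
        for col in frame.columns:
            if col == "person":
                continue
            var, _, t = col.rpartition(sep)
            if var not in names or not t.isdigit():
                raise ValueError(f"unknown column {col!r}")
            parsed.append((var, int(t), col))
        K = max(t for _, t, _ in parsed)
        values = {name: np.full((len(persons), K + 1), np.nan) for name in names}
        for var, t, col in parsed:
            values[var][:, t] = frame[col].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    return make_panel(persons, _schema_to_roles(schema), values, K)


def _schema_to_roles(schema: dict) -> dict:
    return {
        "outcome": schema["outcome"],
        "treatment": schema["treatment"],
        "confounders": list(schema.get("confounders", [])),
    }


def write_panel(panel: PanelData, path, layout: str = "long", sep: str = "_"):
    if layout == "long":
        rows = []
        for name in panel.variable_names:
            mat = panel.values[name]
            for k in panel.waves[name]:
                col = mat[:, k]
                ok = np.isfinite(col)
                rows.append(
                    pd.DataFrame(
                        {
                            "person": panel.person_ids[ok],
                            "time": k,
                            "variable": name,
                            "value": col[ok],
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    elif layout == "wide":
        data = {"person": panel.person_ids}
        for name in panel.variable_names:
            for k in panel.waves[name]:
                data[f"{name}{sep}{k}"] = panel.values[name][:, k]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


# -- validation ------------------------------------------------------------

@dataclass
class PanelReport:
    n_persons: int
    K: int
    missing_rates: dict[str, float]
    per_person_observed: np.ndarray  # P_i: observed cells per person
    constant_columns: list[tuple[str, int]] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"panel: N={self.n_persons}, K={self.K}"]
        for name, rate in self.missing_rates.items():
            lines.append(f"  {name}: missing rate {rate:.3f}")
        if self.constant_columns:
            lines.append(f"  constant columns: {self.constant_columns}")
        return "\n".join(lines)


def validate_panel(panel: PanelData) -> PanelReport:
    """Report-only diagnostics; never mutates the panel."""
    missing_rates = {}
    observed = np.zeros(panel.n_persons, dtype=int)
    constant = []
    for name in panel.variable_names:
        mat = panel.variable_matrix(name)
        missing_rates[name] = float(np.isnan(mat).mean())
        observed += np.isfinite(mat).sum(axis=1)
        for j, k in enumerate(panel.waves[name]):
            col = mat[:, j]
            col = col[np.isfinite(col)]
            if col.size and np.ptp(col) == 0:
                constant.append((name, k))
    return PanelReport(
        n_persons=panel.n_persons,
        K=panel.K,
        missing_rates=missing_rates,
        per_person_observed=observed,
        constant_columns=constant,
    )


# -- score I/O -------------------------------------------------------------

def write_scores(scores, path):
    """Write a ScoreSet as long CSV (person, time, variable, within_score,
    stable_trait).  Rows for missing cells are omitted."""
    rows = []
    for name in scores.variable_names:
        mat = scores.within_scores[name]
        traits = scores.stable_traits.get(name)
        for j, k in enumerate(scores.waves[name]):
            col = mat[:, j]
            ok = np.isfinite(col)
            rows.append(
                pd.DataFrame(
                    {
                        "person": scores.person_ids[ok],
                        "time": k,
                        "variable": name,
                        "within_score": col[ok],
                        "stable_trait": traits[ok] if traits is not None else np.nan,
                    }
                )
            )
    frame = pd.concat(rows, ignore_index=True)
    frame.to_csv(path, index=False)
    return path


def read_scores(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"person", "time", "variable", "within_score"}
    if not required.issubset(frame.columns):
        raise ValueError(f"score file needs columns {sorted(required)}")
    return frame
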