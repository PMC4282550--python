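"""Patient-level trial data: validation, derived log size ratios, success labels, I/O.

A trial dataset holds one row per patient with the summed target-lesion
diameter (``z``, in cm) at baseline, interim and final visits, together with
indicators of *non-shrinkage failure* (progression by new lesions, non-target
growth, toxicity or death) in each inter-visit interval and of non-failure
dropout.  The continuous outcome actually modelled is the log tumour-size
ratio ``y_k = log(z_k / z_0)``.

Missingness is structural and monotone: a patient who fails in interval 1 has
no interim or final size and no interval-2 failure status; a patient who drops
out before a visit has everything from that visit onwards missing.  An
indicator value of 0 is informative ("at risk and did not fail") and is never
conflated with a missing value, so indicators are carried as floats with NaN
for missing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "PatientRecord",
    "TrialData",
    "TrialValidationError",
    "log_tumour_ratio",
    "label_success",
    "read_trial",
    "write_trial",
]

#: canonical column order of the delimited-file schema
COLUMNS = ["id", "arm", "z0", "z1", "z2", "d1", "d2", "drop1", "drop2"]

_SIZE_COLS = ["z0", "z1", "z2"]
_IND_COLS = ["d1", "d2", "drop1", "drop2"]


class TrialValidationError(ValueError):
    """Raised when a trial table violates the patient-record invariants.

    Carries one message per offending row so a malformed file can be fixed in
    a single pass.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid trial data:\n  " + "\n  ".join(self.problems)
        )


@dataclass
class PatientRecord:
    """One subject: sizes in cm, failure/dropout indicators, arm.

    ``None`` encodes a missing value.  ``arm`` is 0 for single-arm trials.
    """

    id: str
    z0: float
    arm: int = 0
    z1: float | None = None
    z2: float | None = None
    d1: int | None = None
    d2: int | None = None
    drop1: int | None = 0
    drop2: int | None = None

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in COLUMNS}


def _as_float(x):
    return np.nan if x is None else float(x)


class TrialData:
    """Validated trial table with derived log tumour-size ratios.

    Parameters
    ----------
    table : pandas.DataFrame or iterable of PatientRecord
        Must provide the columns of :data:`COLUMNS` (``id`` optional; generated
        if absent).  Empty/NaN cells are missing values.
    validate : bool
        Enforce the record invariants (default).  Disable only for
        deliberately malformed fixtures.

    Attributes
    ----------
    y1, y2 : ndarray
        Log tumour-size ratios at interim and final visit, NaN where the size
        is missing.  A complete response (size 0) is substituted by the lowest
        observed ratio of all other patients at that timepoint, keeping the
        ratio finite on the log scale.
    """

    def __init__(self, table, validate: bool = True):
        if isinstance(table, TrialData):
            table = table.df
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame([r.to_dict() for r in table])
        df = table.copy().reset_index(drop=True)
        if "id" not in df.columns:
            df["id"] = [f"P{i + 1:04d}" for i in range(len(df))]
        if "arm" not in df.columns:
            df["arm"] = 0
        missing_cols = [c for c in COLUMNS if c not in df.columns]
        if missing_cols:
            raise TrialValidationError(
                [f"missing required column(s): {', '.join(missing_cols)}"]
            )
        df = df[COLUMNS]
        df["id"] = df["id"].astype(str)
        for c in _SIZE_COLS + _IND_COLS:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        df["arm"] = df["arm"].astype(int)
        if validate:
            problems = _check_invariants(df)
            if problems:
                raise TrialValidationError(problems)
        self._df = df
        self.y1 = _derive_log_ratio(df, "z1")
        self.y2 = _derive_log_ratio(df, "z2")

    # -- basic container surface -------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def arm(self) -> np.ndarray:
        return self._df["arm"].to_numpy()

    @property
    def z0(self) -> np.ndarray:
        return self._df["z0"].to_numpy()

    def col(self, name: str) -> np.ndarray:
        return self._df[name].to_numpy()

    @property
    def comparative(self) -> bool:
        """True iff both arms are non-empty."""
        arms = set(self._df["arm"].unique())
        return arms == {0, 1}

    def subset(self, mask) -> "TrialData":
        return TrialData(self._df.loc[np.asarray(mask)], validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialData):
            return NotImplemented
        return self._df.equals(other._df)


def _check_invariants(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []

    def bad(mask, msg):
        for i in np.flatnonzero(np.asarray(mask)):
            problems.append(f"row {i} (id={df['id'].iloc[i]}): {msg}")

    obs = {c: df[c].notna().to_numpy() for c in _SIZE_COLS + _IND_COLS}
    v = {c: df[c].to_numpy() for c in _SIZE_COLS + _IND_COLS}

    bad(~obs["z0"], "baseline size z0 is required")
    bad(obs["z0"] & ~(v["z0"] > 0), "baseline size z0 must be > 0")
    for c in ("z1", "z2"):
        bad(obs[c] & (v[c] < 0), f"{c} must be >= 0")
    for c in _IND_COLS:
        bad(obs[c] & ~np.isin(v[c], (0.0, 1.0)), f"{c} must be 0, 1 or empty")
    bad(~np.isin(df["arm"].to_numpy(), (0, 1)), "arm must be 0 or 1")

    d1_fail = obs["d1"] & (v["d1"] == 1)
    bad(d1_fail & obs["z1"], "d1=1 but interim size z1 present")
    bad(d1_fail & obs["z2"], "d1=1 but final size z2 present")
    bad(d1_fail & obs["d2"], "d1=1 but d2 present")

    d2_fail = obs["d2"] & (v["d2"] == 1)
    bad(d2_fail & obs["z2"], "d2=1 but final size z2 present")

    dr1 = obs["drop1"] & (v["drop1"] == 1)
    for c in ("z1", "z2", "d1", "d2"):
        bad(dr1 & obs[c], f"drop1=1 but {c} present")
    dr2 = obs["drop2"] & (v["drop2"] == 1)
    for c in ("z2", "d2"):
        bad(dr2 & obs[c], f"drop2=1 but {c} present")

    d2_obs = obs["d2"]
    bad(d2_obs & ~(obs["d1"] & (v["d1"] == 0)), "d2 present requires d1=0")
    bad(d2_obs & obs["drop1"] & (v["drop1"] == 1), "d2 present requires drop1=0")
    return problems


def log_tumour_ratio(z0: float, zt: float, floor_ratio: float | None = None) -> float:
    """Log tumour-size ratio ``log(zt / z0)``.

    A complete response (``zt == 0``) has no finite log ratio; the convention
    is to substitute the lowest observed size ratio among all *other* patients
    at the same timepoint, supplied here as ``floor_ratio``.
    """
    if z0 <= 0:
        raise ValueError("baseline size must be positive")
    if zt < 0:
        raise ValueError("tumour size must be non-negative")
    if zt == 0:
        if floor_ratio is None or not floor_ratio > 0:
            raise ValueError(
                "size 0 (complete response) needs a positive floor_ratio "
                "taken from the other patients' observed ratios"
            )
        return math.log(floor_ratio)
    return math.log(zt / z0)


def _derive_log_ratio(df: pd.DataFrame, col: str) -> np.ndarray:
    z = df[col].to_numpy(float)
    z0 = df["z0"].to_numpy(float)
    y = np.full(len(df), np.nan)
    pos = np.isfinite(z) & (z > 0)
    y[pos] = np.log(z[pos] / z0[pos])
    zeros = np.flatnonzero(np.isfinite(z) & (z == 0))
    for i in zeros:
        others = pos.copy()
        others[i] = False
        if not others.any():
            raise TrialValidationError(
                [
                    f"row {i} (id={df['id'].iloc[i]}): complete response in "
                    f"{col} but no other patient has an observed ratio to "
                    "substitute"
                ]
            )
        y[i] = math.log(np.min(z[others] / z0[others]))
    return y


def label_success(
    data: TrialData,
    final_threshold: float = 0.7,
    interim_threshold: float | None = None,
) -> np.ndarray:
    """Composite success label per patient: 1, 0 or NaN (undeterminable).

    Success requires no non-shrinkage failure in either interval and a final
    size ratio below ``final_threshold`` (0.7 for an ORR-like endpoint, 1.2
    for DCR-like).  With ``interim_threshold`` set (case-study variant), the
    interim ratio must additionally be below that threshold.  The label is 0
    as soon as any *observed* criterion fails, and missing only when dropout
    leaves the status undeterminable.
    """
    for name, thr in (("final", final_threshold), ("interim", interim_threshold)):
        if thr is not None and thr <= 0:
            raise ValueError(f"{name}_threshold must be > 0")
    d1 = data.col("d1")
    d2 = data.col("d2")
    y1, y2 = data.y1, data.y2
    lc = math.log(final_threshold)

    failed = (d1 == 1) | (d2 == 1) | (~np.isnan(y2) & (y2 >= lc))
    success = (d1 == 0) & (d2 == 0) & ~np.isnan(y2) & (y2 < lc)
    if interim_threshold is not None:
        li = math.log(interim_threshold)
        failed |= ~np.isnan(y1) & (y1 >= li)
        success &= ~np.isnan(y1) & (y1 < li)
    return np.where(failed, 0.0, np.where(success, 1.0, np.nan))


def read_trial(path) -> TrialData:
    """Read a trial CSV (RFC-4180, header row, empty cell = missing)."""
    df = pd.read_csv(path, dtype={"id": str})
    return TrialData(df)


def write_trial(data: TrialData, path) -> None:
    """Write a trial CSV that round-trips through :func:`read_trial`."""
    out = data.df.copy()
    for c in _IND_COLS:
        out[c] = out[c].map(lambda x: "" if pd.isna(x) else str(int(x)))
    out.to_csv(path, index=False, na_rep="")


def export_json(obj: dict, path=None) -> str:
    """Serialise a fitted-result dictionary to JSON (file or string)."""
    text = json.dumps(obj, indent=2, default=_json_default)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _json_default(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serialisable: {type(x)!r}")
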