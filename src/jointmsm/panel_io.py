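"""Long-format panel datasets, transition tables and cohort summaries.

The on-disk format is a comma-separated UTF-8 file with a header row and one
row per patient x joint location x side x clinic visit::

    patient_id,location,side,visit,time,damage,tender_only,effused

Times are decimal years since clinic entry (6 digits); ``damage`` is the
irreversible clinical-damage indicator; ``tender_only`` and ``effused`` are
the two mutually exclusive levels of observed joint activity (both 0 means
inactive; empty cells mean activity was not recorded and trigger patient-level
complete-case filtering in analyses that use activity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import DataValidityError
from .model_spec import JOINT_LOCATIONS

COLUMNS = [
    "patient_id", "location", "side", "visit", "time",
    "damage", "tender_only", "effused",
]


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in COLUMNS})
    return _normalize(df)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(np.int64)
    df["location"] = df["location"].astype(str)
    df["side"] = df["side"].astype(str)
    df["visit"] = df["visit"].astype(np.int64)
    df["time"] = df["time"].astype(float).round(6)
    df["damage"] = df["damage"].astype(np.int64)
    df["tender_only"] = df["tender_only"].astype(float)
    df["effused"] = df["effused"].astype(float)
    return df.sort_values(["patient_id", "location", "side", "visit"]).reset_index(drop=True)


class PanelDataset:
    """A validated long-format panel of hand-joint observations."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if df.empty:
            self.df = _empty_frame()
        else:
            missing = [c for c in COLUMNS if c not in df.columns]
            if missing:
                raise DataValidityError(f"panel is missing columns {missing}")
            self.df = _normalize(df[COLUMNS])
        if validate:
            self._validate()

    # -- invariants --------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        if df.empty:
            return
        bad_loc = set(df["location"]) - set(JOINT_LOCATIONS)
        if bad_loc:
            raise DataValidityError(f"unknown joint locations {sorted(bad_loc)}")
        bad_side = set(df["side"]) - {"L", "R"}
        if bad_side:
            raise DataValidityError(f"unknown sides {sorted(bad_side)}; use 'L'/'R'")
        for col in ("damage",):
            if not df[col].isin([0, 1]).all():
                raise DataValidityError(f"{col} must be 0/1")
        for col in ("tender_only", "effused"):
            ok = df[col].isin([0.0, 1.0]) | df[col].isna()
            if not ok.all():
                raise DataValidityError(f"{col} must be 0/1 or empty")
        both = (df["tender_only"] == 1) & (df["effused"] == 1)
        if both.any():
            row = df[both].iloc[0]
            raise DataValidityError(
                f"tender_only and effused both 1: patient {row.patient_id}, "
                f"joint {row.location}-{row.side}, visit {row.visit}"
            )

        g = df.groupby(["patient_id", "location", "side"], sort=False)
        if (g["visit"].apply(lambda v: v.duplicated().any())).any():
            raise DataValidityError("duplicated visit indices within a joint")
        dt = g["time"].diff()
        if (dt.dropna() <= 0).any():
            row = df[dt <= 0].iloc[0]
            raise DataValidityError(
                f"visit times not strictly increasing: patient {row.patient_id}, "
                f"joint {row.location}-{row.side}, visit {row.visit}"
            )
        dd = g["damage"].diff()
        if (dd.dropna() < 0).any():
            row = df[dd < 0].iloc[0]
            raise DataValidityError(
                f"damage reversal: patient {row.patient_id}, joint "
                f"{row.location}-{row.side}, visit {row.visit}"
            )
        # one common visit schedule per patient across all joints
        sched = df.groupby(["patient_id", "visit"])["time"].nunique()
        if (sched > 1).any():
            pid = sched[sched > 1].index[0][0]
            raise DataValidityError(
                f"patient {pid}: joints disagree on the visit schedule"
            )

    # -- basic properties --------------------------------------------------

    @property
    def patients(self) -> np.ndarray:
        return np.sort(self.df["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return int(self.df["patient_id"].nunique())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)

    # -- missing activity --------------------------------------------------

    def complete_case(self) -> Tuple["PanelDataset", list]:
        """Drop patients with any unrecorded activity (patient-level filter).

        Mirrors the study's exclusion of patients with missing activity
        information; missing values are never imputed.
        """
        has_na = self.df["tender_only"].isna() | self.df["effused"].isna()
        excluded = sorted(self.df.loc[has_na, "patient_id"].unique().tolist())
        if not excluded:
            return self, []
        keep = ~self.df["patient_id"].isin(excluded)
        return PanelDataset(self.df[keep], validate=False), excluded

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path) -> None:
        out = self.df.copy()
        out["time"] = out["time"].map(lambda t: f"{t:.6f}")
        for col in ("tender_only", "effused"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PanelDataset":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return cls(pd.DataFrame(), validate=False)
        if df.empty:
            return cls(pd.DataFrame(), validate=False)
        return cls(df)


# ---------------------------------------------------------------------------
# transition tables


@dataclass
class TransitionTable:
    """Counts of consecutive-visit state pairs for one model view."""

    counts: np.ndarray
    labels: Tuple[str, ...]
    view: str  # "four_state" | "three_state"

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


FOUR_STATE_LABELS = ("neither", "right only", "left only", "both")
THREE_STATE_LABELS = ("inactive", "active", "damaged")


def _paired_states(ds: PanelDataset) -> pd.DataFrame:
    """Wide frame: one row per (patient, location, visit) with both sides."""
    df = ds.df
    wide = df.pivot_table(
        index=["patient_id", "location", "visit"],
        columns="side",
        values=["damage", "tender_only", "effused", "time"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    if wide[["damage_L", "damage_R"]].isna().any().any():
        raise DataValidityError("each joint location needs both L and R rows")
    wide = wide.reset_index().sort_values(["patient_id", "location", "visit"])
    wide["state"] = (
        1 + wide["damage_R"].astype(int) + 2 * wide["damage_L"].astype(int)
    )
    return wide


def four_state_table(ds: PanelDataset) -> TransitionTable:
    """Observed transitions of the paired-damage (four-state) view.

    State 1 neither joint damaged, 2 right only, 3 left only, 4 both.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    if not ds.df.empty:
        wide = _paired_states(ds)
        grp = wide.groupby(["patient_id", "location"], sort=False)["state"]
        cur = wide["state"].to_numpy()
        nxt = grp.shift(-1).to_numpy()
        ok = ~np.isnan(nxt)
        np.add.at(counts, (cur[ok] - 1, nxt[ok].astype(int) - 1), 1)
    return TransitionTable(counts, FOUR_STATE_LABELS, "four_state")


def _joint_states(ds: PanelDataset) -> pd.DataFrame:
    """Per-joint three-state sequences, truncated at first observed damage."""
    df, _ = ds.complete_case()
    df = df.df
    active = (df["tender_only"] == 1) | (df["effused"] == 1)
    state = np.where(df["damage"] == 1, 3, np.where(active, 2, 1))
    out = df[["patient_id", "location", "side", "visit", "time"]].copy()
    out["state"] = state
    # follow-up for a joint stops at the visit where damage is first observed
    grp = out.groupby(["patient_id", "location", "side"], sort=False)
    damaged_before = grp["state"].transform(lambda s: (s == 3).shift(1, fill_value=False).cummax())
    return out[~damaged_before.astype(bool)]


def three_state_table(ds: PanelDataset) -> TransitionTable:
    """Observed transitions of the per-joint activity-damage (3-state) view.

    Patients with unrecorded activity are excluded (complete-case filter);
    each joint's sequence stops at the first visit where damage is observed.
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    if not ds.df.empty:
        js = _joint_states(ds)
        grp = js.groupby(["patient_id", "location", "side"], sort=False)["state"]
        cur = js["state"].to_numpy()
        nxt = grp.shift(-1).to_numpy()
        ok = ~np.isnan(nxt)
        np.add.at(counts, (cur[ok] - 1, nxt[ok].astype(int) - 1), 1)
    return TransitionTable(counts, THREE_STATE_LABELS, "three_state")


def table_summaries(table: TransitionTable, joints_at_risk: Optional[int] = None) -> dict:
    """Derived summaries of a transition table.

    ``joints_damaged`` counts newly damaged individual joints: in the
    four-state view one per 1->2, 1->3, 2->4 or 3->4 transition and *two* per
    observed 1->4 transition (both joints of the pair damaged within one
    interval); in the three-state view, all transitions into the damage state.
    """
    c = table.counts
    grand = int(c.sum())
    off = int(c.sum() - np.trace(c))
    if table.view == "four_state":
        damaged = int(c[0, 1] + c[0, 2] + c[1, 3] + c[2, 3] + 2 * c[0, 3])
    elif table.view == "three_state":
        damaged = int(c[0, 2] + c[1, 2])
    else:
        raise ValueError(f"unknown table view {table.view!r}")
    out = {
        "grand_total": grand,
        "off_diagonal": off,
        "joints_damaged": damaged,
    }
    if joints_at_risk is not None:
        out["joints_at_risk"] = int(joints_at_risk)
        out["damaged_fraction"] = damaged / joints_at_risk if joints_at_risk else 0.0
    return out


def cohort_summaries(ds: PanelDataset, metadata: Optional[pd.DataFrame] = None) -> dict:
    """Descriptive statistics of a cohort panel.

    ``metadata`` may carry one row per patient with columns ``patient_id`` and
    ``sex`` ("M"/"F"); sex percentages are then reported to one decimal.
    Gap-time statistics pool all inter-visit gaps across patients.
    Hand-joint-years run from entry to the first visit with observed damage,
    or to the last visit, per joint.
    """
    out: dict = {
        "n_patients": ds.n_patients,
        "joints_at_risk": 28 * ds.n_patients,
    }
    df = ds.df
    if df.empty:
        out.update(
            visits_median=0, visits_min=0, visits_max=0,
            gap_mean_years=None, gap_median_years=None,
            hand_joint_years=0.0, joints_damaged=0,
            damage_rate_per_1000_joint_years=None,
        )
    else:
        sched = df.groupby("patient_id")["visit"].nunique()
        out["visits_median"] = float(sched.median())
        out["visits_min"] = int(sched.min())
        out["visits_max"] = int(sched.max())
        times = df.drop_duplicates(["patient_id", "visit"]).sort_values(
            ["patient_id", "visit"]
        )
        gaps = times.groupby("patient_id")["time"].diff().dropna()
        out["gap_mean_years"] = float(gaps.mean())
        out["gap_median_years"] = float(gaps.median())

        keys = ["patient_id", "location", "side"]
        grp = df.groupby(keys, sort=False)
        fu = grp["time"].last()
        first_dmg = df[df["damage"] == 1].groupby(keys, sort=False)["time"].first()
        fu.loc[first_dmg.index] = first_dmg
        damaged_joints = int(grp["damage"].max().sum())
        out["hand_joint_years"] = float(fu.sum())
        out["joints_damaged"] = damaged_joints
        out["damage_rate_per_1000_joint_years"] = (
            1000.0 * damaged_joints / fu.sum() if fu.sum() > 0 else None
        )
    if metadata is not None and len(metadata):
        meta = metadata.drop_duplicates("patient_id")
        n = len(meta)
        male = int((meta["sex"] == "M").sum())
        out["n_male"] = male
        out["n_female"] = n - male
        out["percent_male"] = round(100.0 * male / n, 1)
        out["percent_female"] = round(100.0 * (n - male) / n, 1)
    return out


def joints_at_risk(n_patients: int) -> int:
    """28 hand joints per patient."""
    return 28 * n_patients
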