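"""Clotting-assay records and validation against NE-decrease predictions.

The three clinical assays — activated partial thromboplastin time
(aPTT), prothrombin time (PT) and thrombin time (TT) — probe the
intrinsic, extrinsic and final common pathway respectively.  Each is
summarised as a prolongation ratio

    delta = (t_sample - t_control) / t_control

and the sum of the three ratios is taken as a whole-cascade activity
readout, to be correlated (Pearson) with the predicted NE decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats

from .estimation import CompoundEstimate

__all__ = [
    "AssayRecord",
    "ValidationReport",
    "delta_ratio",
    "activity_sum",
    "pearson_correlation",
    "load_assay_table",
    "table1_fixture",
    "validate",
    "validate_against_target",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayRecord:
    """Per-compound prolongation ratios of the three clotting assays."""

    compound: str
    delta_aptt_ratio: float
    delta_pt_ratio: float
    delta_tt_ratio: float

    def __post_init__(self) -> None:
        for name in ("delta_aptt_ratio", "delta_pt_ratio", "delta_tt_ratio"):
            v = getattr(self, name)
            if v is None or pd.isna(v):
                raise ValueError(f"{self.compound}: missing {name}")
            if v < -1:
                raise ValueError(
                    f"{self.compound}: {name} = {v} below -1 "
                    "(clot time cannot be negative)"
                )

    @property
    def activity_sum(self) -> float:
        return self.delta_aptt_ratio + self.delta_pt_ratio + self.delta_tt_ratio


@dataclass(frozen=True)
class ValidationReport:
    """Pearson correlation between activity sums and NE decreases."""

    n: int
    pearson_r: float
    pairs: pd.DataFrame  # columns: compound, activity_sum, ne_decrease


def delta_ratio(t_sample: float, t_control: float) -> float:
    """Prolongation ratio of a clot time against its vehicle control."""
    if not t_control > 0:
        raise ValueError(f"control clot time must be positive, got {t_control}")
    return (t_sample - t_control) / t_control


def activity_sum(record: AssayRecord) -> float:
    """Sum of the three assay ratios: the whole-cascade activity readout."""
    return record.activity_sum


def pearson_correlation(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = pd.Series(list(x), dtype=float)
    y = pd.Series(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(x, y).statistic)


def _records_from_deltas(df: pd.DataFrame) -> list[AssayRecord]:
    records = []
    for row in df.itertuples():
        vals = (row.delta_aptt, row.delta_pt, row.delta_tt)
        if any(pd.isna(v) for v in vals):
            logger.warning("compound %s: missing assay ratio; row excluded",
                           row.compound)
            continue
        records.append(AssayRecord(str(row.compound), *map(float, vals)))
    return records


def load_assay_table(path: str | Path) -> list[AssayRecord]:
    """Load assay records from a delimited file.

    Two layouts are accepted: precomputed ratios with columns
    ``compound, delta_aptt, delta_pt, delta_tt`` or raw clot times with
    columns ``compound, assay, t_sample, t_control`` (one row per assay;
    assay in {aptt, pt, tt}).  Rows with any missing ratio are excluded
    with a logged warning, not zero-filled.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if {"compound", "delta_aptt", "delta_pt", "delta_tt"} <= set(df.columns):
        return _records_from_deltas(df)
    if {"compound", "assay", "t_sample", "t_control"} <= set(df.columns):
        df["assay"] = df["assay"].str.strip().str.lower()
        bad = set(df["assay"]) - {"aptt", "pt", "tt"}
        if bad:
            raise ValueError(f"unknown assay name(s): {sorted(bad)}")
        wide = df.pivot_table(
            index="compound", columns="assay", aggfunc="first"
        )
        records = []
        for compound in wide.index:
            ratios = {}
            for assay in ("aptt", "pt", "tt"):
                try:
                    ts = wide.at[compound, ("t_sample", assay)]
                    tc = wide.at[compound, ("t_control", assay)]
                except KeyError:
                    ts = tc = float("nan")
                if pd.isna(ts) or pd.isna(tc):
                    ratios = None
                    break
                ratios[assay] = delta_ratio(float(ts), float(tc))
            if ratios is None:
                logger.warning("compound %s: incomplete assays; excluded", compound)
                continue
            records.append(
                AssayRecord(str(compound), ratios["aptt"], ratios["pt"], ratios["tt"])
            )
        return records
    raise ValueError(
        "unrecognised assay table layout: need either delta_* columns or "
        "assay/t_sample/t_control columns"
    )


def table1_fixture(frame: bool = False):
    """Packaged validation table for the fourteen assayed compounds.

    With ``frame=False`` (default) returns the list of
    :class:`AssayRecord`; with ``frame=True`` returns the full DataFrame
    including the published sum column (kept verbatim) and the published
    NE decreases.
    """
    data = resources.files("cascade_ne").joinpath("data/table1_assays.tsv")
    with resources.as_file(data) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    if frame:
        return df
    return _records_from_deltas(
        df.rename(columns={"delta_aptt": "delta_aptt", "delta_pt": "delta_pt"})
    )


def validate(
    estimates: list[CompoundEstimate], assays: list[AssayRecord]
) -> ValidationReport:
    """Correlate predicted NE decreases with summed assay activities.

    Inner-joins on compound id (ids unmatched on either side are logged)
    and reports the pair count, the Pearson r and the paired series.
    Fewer than 3 common compounds is an error.
    """
    est = {e.compound: e.ne_decrease for e in estimates}
    act = {a.compound: a.activity_sum for a in assays}
    common = sorted(est.keys() & act.keys())
    for missing in sorted(est.keys() ^ act.keys()):
        logger.warning("compound %s present on one side only; excluded", missing)
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 compounds common to estimates and assays, got {len(common)}"
        )
    pairs = pd.DataFrame(
        {
            "compound": common,
            "activity_sum": [act[c] for c in common],
            "ne_decrease": [est[c] for c in common],
        }
    )
    r = pearson_correlation(pairs["activity_sum"], pairs["ne_decrease"])
    return ValidationReport(len(common), r, pairs)


def validate_against_target(
    table, assays: list[AssayRecord], target: str
) -> ValidationReport:
    """Single-target comparison: correlate |BE| on one target with activity.

    The multi-target NE decrease is replaced by the binding-energy
    magnitude on a single named target — the conventional single-target
    virtual-screening baseline the network approach is compared against.
    """
    from .network import normalize_node_id

    target = normalize_node_id(target)
    sub = table.frame[table.frame["target"] == target]
    if sub.empty:
        raise KeyError(f"no scores for target {target!r}")
    est = [
        CompoundEstimate(str(row.compound), 0.0, abs(row.binding_energy), 0)
        for row in sub.itertuples()
    ]
    return validate(est, assays)
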