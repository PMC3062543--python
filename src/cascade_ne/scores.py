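"""Docking-score tables and the line-value transformation.

A docking run produces, for each (compound, target) pair, a predicted
binding free energy BE in kcal/mol (negative = favourable).  For each
target the most potent observed energy BEs serves as the reference: a
compound binding a target as strongly as the reference stretches every
out-edge of that target from the baseline length 10 to 10^2.3 ≈ 200,
and weaker binders stretch them less:

    LV = 10 ** (exponent_factor * |BE| / |BEs|),   exponent_factor = 2.3

Raw LV values below the baseline line value (weak or non-binders, for
which the formula gives 10^x with x < 1) are floored at 10 so that a
non-binder leaves the network unchanged; the floor can be disabled for
fidelity experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .network import DEFAULT_LINE_VALUE, PathwayNetwork, normalize_node_id

__all__ = [
    "TransformConfig",
    "DockingScoreTable",
    "ReferenceEnergy",
    "load_scores",
    "reference_energies",
    "line_value",
    "reweight_for_compound",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("compound", "target", "binding_energy")


@dataclass(frozen=True)
class TransformConfig:
    """Tunables of the binding-energy -> line-value transformation."""

    exponent_factor: float = 2.3
    lv_floor: float | None = DEFAULT_LINE_VALUE
    clamp_positive: bool = True


@dataclass
class DockingScoreTable:
    """Long-form compound x target binding-energy table.

    After construction every stored ``binding_energy`` is <= 0 (positive
    docking scores are clamped to 0 when ``clamp_positive`` is set) and
    (compound, target, stage) combinations are unique.
    """

    frame: pd.DataFrame
    n_clamped: int = 0

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, clamp_positive: bool = True
    ) -> "DockingScoreTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"score table missing column(s): {missing}")
        df = frame.copy()
        if "stage" not in df.columns:
            df["stage"] = "other"
        df["compound"] = df["compound"].astype(str)
        df["target"] = df["target"].map(normalize_node_id)
        energies = pd.to_numeric(df["binding_energy"], errors="coerce")
        if energies.isna().any():
            bad = df.index[energies.isna()][0]
            raise ValueError(
                f"non-numeric binding energy in row {bad}: "
                f"{df.loc[bad].to_dict()}"
            )
        df["binding_energy"] = energies.astype(float)
        dup = df.duplicated(subset=["compound", "target", "stage"])
        if dup.any():
            rows = df.loc[dup, ["compound", "target", "stage"]]
            raise ValueError(
                f"duplicate (compound, target, stage) rows: "
                f"{rows.to_records(index=False).tolist()}"
            )
        n_clamped = 0
        if clamp_positive:
            pos = df["binding_energy"] > 0
            n_clamped = int(pos.sum())
            if n_clamped:
                logger.info("clamped %d positive docking score(s) to 0", n_clamped)
                df.loc[pos, "binding_energy"] = 0.0
        elif (df["binding_energy"] > 0).any():
            raise ValueError("positive binding energies present and clamping disabled")
        return cls(df.reset_index(drop=True), n_clamped)

    @property
    def compounds(self) -> list[str]:
        return sorted(self.frame["compound"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.frame["target"].unique())

    def for_compound(self, compound: str) -> pd.DataFrame:
        sub = self.frame[self.frame["compound"] == str(compound)]
        if sub.empty:
            raise KeyError(f"compound {compound!r} not in score table")
        return sub

    def subset(self, compounds: list[str]) -> "DockingScoreTable":
        keep = {str(c) for c in compounds}
        missing = keep - set(self.frame["compound"])
        if missing:
            raise KeyError(f"compounds not in score table: {sorted(missing)}")
        sub = self.frame[self.frame["compound"].isin(keep)]
        return DockingScoreTable(sub.reset_index(drop=True), self.n_clamped)


@dataclass(frozen=True)
class ReferenceEnergy:
    """Per-target reference energies BEs (most potent observed binder)."""

    energies: dict[str, float] = field(default_factory=dict)
    degenerate: frozenset[str] = frozenset()

    def __getitem__(self, target: str) -> float:
        return self.energies[normalize_node_id(target)]


def load_scores(
    path: str | Path, clamp_positive: bool = True
) -> DockingScoreTable:
    """Load a delimited compound/target/binding_energy[,stage] table.

    Comma- and tab-separated files are both accepted.  Positive energies
    are clamped to 0 (count logged); duplicate rows are an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    return DockingScoreTable.from_frame(frame, clamp_positive=clamp_positive)


def reference_energies(table: DockingScoreTable) -> ReferenceEnergy:
    """Per-target minimum (most negative = most potent) binding energy.

    Targets whose every score is 0 are flagged degenerate; they cannot
    anchor the line-value transformation.
    """
    if table.frame.empty:
        raise ValueError("empty score table has no reference energies")
    mins = table.frame.groupby("target")["binding_energy"].min()
    energies = {t: float(v) for t, v in mins.items()}
    degenerate = frozenset(t for t, v in energies.items() if v == 0.0)
    return ReferenceEnergy(energies, degenerate)


def line_value(
    be: float, bes: float, config: TransformConfig = TransformConfig()
) -> float:
    """Line value of a target's out-edges for a given binding energy.

    ``LV = 10 ** (exponent_factor * |be| / |bes|)``, floored at
    ``config.lv_floor`` (default 10) when the floor is enabled.  At
    ``be == bes`` this is 10^2.3 ≈ 199.5 (~200), the strongest
    stretching a compound can exert on a target's out-edges.
    """
    if be > 0:
        raise ValueError(f"binding energy must be <= 0 after clamping, got {be}")
    if not bes < 0:
        raise ValueError(
            f"degenerate reference energy {bes!r}: no potent binder for target"
        )
    lv = 10.0 ** (config.exponent_factor * abs(be) / abs(bes))
    if config.lv_floor is not None:
        lv = max(lv, config.lv_floor)
    return lv


def reweight_for_compound(
    net: PathwayNetwork,
    table: DockingScoreTable,
    refs: ReferenceEnergy,
    compound: str,
    config: TransformConfig = TransformConfig(),
) -> PathwayNetwork:
    """Network with each scored target's out-edges set to the compound's LV.

    For every target the compound was docked against, all out-edges of
    that target node take the line value from :func:`line_value`; every
    other edge keeps the baseline value 10.  Targets absent from the
    network (or degenerate) are skipped with a warning in the log.  The
    input network is not modified.
    """
    new_values: dict[tuple[str, str], float] = {}
    for row in table.for_compound(compound).itertuples():
        target = row.target
        if target not in net:
            logger.warning(
                "compound %s: scored target %r absent from network; skipped",
                compound,
                target,
            )
            continue
        if target in refs.degenerate:
            logger.warning(
                "compound %s: target %r has degenerate reference; skipped",
                compound,
                target,
            )
            continue
        lv = line_value(row.binding_energy, refs[target], config)
        for u, v in net.out_edges(target):
            new_values[(u, v)] = lv
    return net.with_line_values(new_values)
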