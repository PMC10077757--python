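"""Reading, validation and normalization of viability-screen tables.

Screen tables are long-format CSV/TSV files with one well per row:

``cell_line, compound, dose, unit, replicate, signal, role``

plus ``anchor_compound, anchor_dose`` for the combination schema.  Doses
are converted to nM on read.  ``role`` distinguishes treated wells
(``sample``) from the plate controls: DMSO-treated wells anchor 100%
viability (``pos_control``) and empty (or kill-control) wells anchor 0%
(``neg_control``).  Which physical well type plays the negative control
is a data-preparation concern, not a code branch.

Viability is computed per plate group as

    v = (signal - mean(neg)) / (mean(pos) - mean(neg))

and deliberately *not* clipped: values above 1 (noise above the DMSO
mean) carry information for least-squares fitting.  Clipping to [0, 1]
happens only where a downstream formula requires a fraction (Bliss).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from synscreen.errors import (
    DegeneratePlateError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ROLES = ("sample", "pos_control", "neg_control")

MONOTHERAPY_COLUMNS = [
    "cell_line", "compound", "dose", "unit", "replicate", "signal", "role",
]
COMBINATION_COLUMNS = MONOTHERAPY_COLUMNS + ["anchor_compound", "anchor_dose"]

SCHEMAS: Mapping[str, list[str]] = {
    "monotherapy": MONOTHERAPY_COLUMNS,
    "combination": COMBINATION_COLUMNS,
}

#: Conversion factors to nM.
UNIT_TO_NM = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


@dataclass(frozen=True)
class WellRecord:
    """A single validated well of a screen plate.

    Doses are in nM; ``dose`` is the (library) compound concentration and
    ``anchor_dose`` the fixed partner concentration in combination
    screens (0 for monotherapy wells).  ``signal`` is the raw readout in
    arbitrary units.
    """

    cell_line: str
    compound: str
    dose: float
    replicate: int
    signal: float
    role: str
    anchor_compound: str | None = None
    anchor_dose: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown well role {self.role!r}")
        if not np.isfinite(self.dose) or self.dose < 0:
            raise ValidationError(f"dose must be finite and >= 0, got {self.dose}")
        if not np.isfinite(self.anchor_dose) or self.anchor_dose < 0:
            raise ValidationError(
                f"anchor_dose must be finite and >= 0, got {self.anchor_dose}"
            )
        if self.signal < 0:
            raise ValidationError(f"signal must be >= 0, got {self.signal}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.role == "pos_control" and (self.dose != 0 or self.anchor_dose != 0):
            raise ValidationError("pos_control wells must have all doses == 0")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_screen_table(path: str | Path, schema: str = "monotherapy") -> pd.DataFrame:
    """Read a long-format screen table into the canonical frame.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab, by extension) file.
    schema
        ``"monotherapy"`` or ``"combination"``; selects the required
        column set.

    Returns
    -------
    DataFrame with canonical columns, doses converted to nM and the
    ``unit`` column dropped.  Row count equals the file's data rows.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {list(SCHEMAS)}")
    df = pd.read_csv(path, sep=_sep_for(path))
    required = SCHEMAS[schema]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path.name}")
    df = df[required].copy()

    bad_unit = set(df["unit"].unique()) - set(UNIT_TO_NM)
    if bad_unit:
        raise ValidationError(f"unknown dose unit(s) {sorted(bad_unit)} in {path.name}")
    df["dose"] = df["dose"].astype(float) * df["unit"].map(UNIT_TO_NM).astype(float)
    df = df.drop(columns=["unit"])

    if schema == "monotherapy":
        df["anchor_compound"] = None
        df["anchor_dose"] = 0.0
    else:
        df["anchor_dose"] = df["anchor_dose"].astype(float)

    df["signal"] = df["signal"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    _validate_frame(df, path.name)
    return df.reset_index(drop=True)


def _validate_frame(df: pd.DataFrame, name: str) -> None:
    neg = np.flatnonzero(df["signal"].to_numpy() < 0)
    if neg.size:
        raise ValidationError(f"negative signal at row {neg[0] + 1} of {name}")
    bad_dose = ~np.isfinite(df["dose"].to_numpy()) | (df["dose"].to_numpy() < 0)
    if bad_dose.any():
        raise ValidationError(
            f"non-finite or negative dose at row {np.flatnonzero(bad_dose)[0] + 1} of {name}"
        )
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        raise ValidationError(
            f"unknown role {df.loc[bad_role, 'role'].iloc[0]!r} in {name}"
        )
    pos = df["role"] == "pos_control"
    if (df.loc[pos, "dose"] != 0).any() or (df.loc[pos, "anchor_dose"] != 0).any():
        raise ValidationError(f"pos_control wells with nonzero dose in {name}")


def write_screen_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical frame back to CSV/TSV (doses emitted in nM)."""
    path = Path(path)
    out = df.copy()
    out.insert(out.columns.get_loc("dose") + 1, "unit", "nM")
    out.to_csv(path, sep=_sep_for(path), index=False)


def to_well_records(df: pd.DataFrame) -> Iterator[WellRecord]:
    """Yield validated :class:`WellRecord` objects from a canonical frame."""
    for row in df.itertuples(index=False):
        anchor = getattr(row, "anchor_compound", None)
        if anchor is not None and (pd.isna(anchor) or anchor == ""):
            anchor = None
        yield WellRecord(
            cell_line=row.cell_line,
            compound=row.compound,
            dose=float(row.dose),
            replicate=int(row.replicate),
            signal=float(row.signal),
            role=row.role,
            anchor_compound=anchor,
            anchor_dose=float(getattr(row, "anchor_dose", 0.0)),
        )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_viability(
    df: pd.DataFrame,
    plate_keys: Iterable[str] = ("cell_line",),
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Normalize raw signals to fractional viability per plate group.

    For every group defined by ``plate_keys`` the mean pos-control
    (DMSO) signal maps to viability 1.0 and the mean neg-control (empty
    well) signal to 0.0.  Sample wells are then optionally averaged over
    replicates within (compound, dose, anchor), retaining the SEM.

    Returns a frame with columns ``cell_line, compound, anchor_compound,
    anchor_dose, dose, viability[, sem, n_rep]``.

    Raises
    ------
    ValidationError
        If a plate group lacks pos or neg controls.
    DegeneratePlateError
        If mean(pos) <= mean(neg) so the viability scale is undefined.
    """
    plate_keys = list(plate_keys)
    out_frames = []
    for key, plate in df.groupby(plate_keys, sort=False):
        pos = plate.loc[plate["role"] == "pos_control", "signal"]
        neg = plate.loc[plate["role"] == "neg_control", "signal"]
        if pos.empty or neg.empty:
            raise ValidationError(
                f"plate group {key!r} lacks pos_control or neg_control wells"
            )
        pos_mean, neg_mean = float(pos.mean()), float(neg.mean())
        if pos_mean <= neg_mean:
            raise DegeneratePlateError(
                f"plate group {key!r}: mean(pos)={pos_mean:.4g} <= mean(neg)={neg_mean:.4g}"
            )
        samples = plate[plate["role"] == "sample"].copy()
        samples["viability"] = (samples["signal"] - neg_mean) / (pos_mean - neg_mean)
        out_frames.append(samples)
    out = pd.concat(out_frames, ignore_index=True)
    point_keys = ["cell_line", "compound", "anchor_compound", "anchor_dose", "dose"]
    if not average_replicates:
        return out[point_keys + ["replicate", "viability"]]
    grouped = out.groupby(point_keys, dropna=False, sort=False)["viability"]
    agg = grouped.agg(viability="mean", sem="sem", n_rep="size").reset_index()
    agg["sem"] = agg["sem"].fillna(0.0)
    return agg


# ---------------------------------------------------------------------------
# Set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class SetCollection:
    """Named sets of member identifiers (compound sets or gene sets).

    Set names are unique; members are de-duplicated within a set while
    preserving first-seen order.  Descriptions round-trip through GMT.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate set name {name!r}")
        deduped = list(dict.fromkeys(members))
        self.sets[name] = deduped
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def items(self):
        return self.sets.items()

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "SetCollection":
        coll = cls()
        for name, members in d.items():
            coll.add(name, members)
        return coll


def read_gmt(path: str | Path) -> SetCollection:
    """Read a GMT file (tab-separated: name, description, members...).

    Lines with no members are skipped with a logged warning; duplicate
    set names are an error; repeated members within a line are
    de-duplicated.
    """
    coll = SetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, description = fields[0], fields[1] if len(fields) > 1 else ""
            members = [m for m in fields[2:] if m]
            if not members:
                logger.warning("GMT line %d (%s): no members, skipped", lineno, name)
                continue
            coll.add(name, members, description)
    return coll


def write_gmt(coll: SetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Sensitivity dataset
# ---------------------------------------------------------------------------

@dataclass
class SensitivityDataset:
    """An AUC matrix (cell lines x compounds) with its metadata.

    ``auc`` holds AUC fractions in [0, 1]; missing entries are NaN,
    never silently zero.  ``cell_meta`` is indexed by cell line and must
    carry a boolean ``pediatric`` flag and a ``tumor_type`` label
    (mutation flags are additional boolean columns).  ``compound_meta``
    is indexed by compound with ``target`` and ``target_pathway``.
    """

    auc: pd.DataFrame
    cell_meta: pd.DataFrame
    compound_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.auc.index.name = "cell_line"
        self.auc.columns.name = "compound"
        if self.auc.index.duplicated().any():
            raise ValidationError("duplicated cell_line identifiers in AUC matrix")
        if self.auc.columns.duplicated().any():
            raise ValidationError("duplicated compound identifiers in AUC matrix")
        for col in ("pediatric", "tumor_type"):
            if col not in self.cell_meta.columns:
                raise SchemaError(f"cell_meta lacks required column {col!r}")
        for col in ("target", "target_pathway"):
            if col not in self.compound_meta.columns:
                raise SchemaError(f"compound_meta lacks required column {col!r}")
        missing_lines = self.auc.index.difference(self.cell_meta.index)
        if len(missing_lines):
            raise ValidationError(
                f"cell lines without metadata: {list(missing_lines[:5])}"
            )
        missing_cmp = self.auc.columns.difference(self.compound_meta.index)
        if len(missing_cmp):
            raise ValidationError(
                f"compounds without metadata: {list(missing_cmp[:5])}"
            )
        vals = self.auc.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValidationError("AUC values must lie in [0, 1]")

    @property
    def cell_lines(self) -> pd.Index:
        return self.auc.index

    @property
    def compounds(self) -> pd.Index:
        return self.auc.columns

    def compound_sets(self, grouping: str = "target_pathway") -> SetCollection:
        """Group compounds by annotation into a :class:`SetCollection`."""
        if grouping not in ("target", "target_pathway"):
            raise ValidationError(f"unknown grouping {grouping!r}")
        coll = SetCollection()
        for label, sub in self.compound_meta.groupby(grouping, sort=True):
            coll.add(str(label), sub.index.tolist())
        return coll

    def write(self, directory: str | Path, prefix: str = "sensitivity") -> None:
        directory = Path(directory)
        self.auc.to_csv(directory / f"{prefix}_auc.tsv", sep="\t",
                        index_label="cell_line")
        self.cell_meta.to_csv(directory / f"{prefix}_cell_meta.tsv", sep="\t",
                              index_label="cell_line")
        self.compound_meta.to_csv(directory / f"{prefix}_compound_meta.tsv", sep="\t",
                                  index_label="compound")

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "sensitivity") -> "SensitivityDataset":
        directory = Path(directory)
        auc = pd.read_csv(directory / f"{prefix}_auc.tsv", sep="\t",
                          index_col="cell_line")
        cell_meta = pd.read_csv(directory / f"{prefix}_cell_meta.tsv", sep="\t",
                                index_col="cell_line")
        compound_meta = pd.read_csv(directory / f"{prefix}_compound_meta.tsv", sep="\t",
                                    index_col="compound")
        return cls(auc=auc, cell_meta=cell_meta, compound_meta=compound_meta)
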