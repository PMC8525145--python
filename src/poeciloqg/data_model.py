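"""Shared data model and tabular I/O.

The package operates on three linked tables:

* a pedigree (individual id, dam, sire, selfed flag) ordered so that
  parents precede their offspring,
* per-clutch egg-mass records (capsule diameters in micrometres, optional
  egg diameters measured before first cleavage),
* a per-individual phenotype table derived from the egg masses (mean
  capsule diameter, binary developmental mode, categorical mode, clutch
  count).

Everything travels as plain UTF-8 CSV so the files diff cleanly; diameters
are micrometres throughout (millimetres appear only in the realized
heritability reporting of capsule size).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CAPSULE_THRESHOLD_UM",
    "SALINITIES",
    "Individual",
    "EggMassRecord",
    "Pedigree",
    "PhenotypeTable",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "load_config",
    "configure_logging",
    "get_logger",
]

#: Capsule diameter (µm) at or above which a capsule develops lecithotrophically.
CAPSULE_THRESHOLD_UM: float = 150.0

SALINITIES = ("low16", "high32")

_PHENOTYPE_COLUMNS = [
    "eggmass_id",
    "individual_id",
    "family",
    "site",
    "dish",
    "salinity",
    "generation",
    "dam",
    "sire",
    "selfed",
    "order_index",
    "capsule_diams",
    "egg_diams",
]

_PEDIGREE_COLUMNS = ["id", "dam", "sire", "selfed"]


def configure_logging(level: int = logging.INFO) -> None:
    """Send module-tagged log lines to stderr (idempotent)."""
    root = logging.getLogger("poeciloqg")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"poeciloqg.{name}")


_log = get_logger("data_model")


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (seeds, chain lengths, thresholds)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


@dataclass(frozen=True)
class Individual:
    """One slug: pedigree links plus experimental placement."""

    id: str
    family: str
    site: str
    dish: str
    salinity: str
    generation: str
    dam: str | None = None
    sire: str | None = None
    selfed: bool = False
    survived_to_lay: bool = True

    def __post_init__(self) -> None:
        if self.salinity not in SALINITIES:
            raise ValueError(
                f"individual {self.id!r}: salinity must be one of {SALINITIES}, "
                f"got {self.salinity!r}"
            )
        if self.selfed and self.dam != self.sire:
            raise ValueError(f"individual {self.id!r}: selfed requires dam == sire")


@dataclass(frozen=True)
class EggMassRecord:
    """One clutch: capsule diameters (µm) and optional pre-cleavage egg diameters."""

    eggmass_id: str
    individual_id: str
    order_index: int
    capsule_diams_um: tuple[float, ...]
    egg_diams_um: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.order_index < 1:
            raise ValueError(f"egg mass {self.eggmass_id!r}: order_index must be >= 1")
        if len(self.capsule_diams_um) == 0:
            raise ValueError(f"egg mass {self.eggmass_id!r}: no capsule diameters")
        for d in self.capsule_diams_um:
            if not d > 0:
                raise ValueError(
                    f"egg mass {self.eggmass_id!r}: capsule diameter {d} not positive"
                )
        if self.egg_diams_um is not None:
            for d in self.egg_diams_um:
                if not d > 0:
                    raise ValueError(
                        f"egg mass {self.eggmass_id!r}: egg diameter {d} not positive"
                    )

    @property
    def mode(self) -> str:
        from .classify import classify_egg_mass

        return classify_egg_mass(self.capsule_diams_um).mode


class Pedigree:
    """Ordered pedigree: parents precede offspring; founders have no parents."""

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals: list[Individual] = list(individuals)
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            for parent in (ind.dam, ind.sire):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"individual {ind.id!r}: parent {parent!r} not previously "
                        "defined in pedigree order"
                    )
            seen.add(ind.id)
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[self._index[ind_id]]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "dam": [i.dam or "" for i in self.individuals],
                "sire": [i.sire or "" for i in self.individuals],
                "selfed": [int(i.selfed) for i in self.individuals],
            }
        )


@dataclass
class PhenotypeTable:
    """Per-individual phenotypes derived from classified egg masses.

    ``y`` is the binary developmental mode (1 = lecithotrophic) scored from
    the individual's mean capsule diameter with the 150 µm boundary assigned
    to lecithotrophy; ``mode`` is the categorical L/P/M call from the
    individual's egg masses (M when the individual laid any mixed clutch or
    clutches of both pure types).
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("individual_id", "mean_capsule_um", "y", "mode", "n_eggmasses")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)


def build_phenotype_table(
    pedigree: Pedigree, records: Sequence[EggMassRecord]
) -> PhenotypeTable:
    """Aggregate egg-mass records into the per-individual phenotype table."""
    from .classify import classify_egg_mass, classify_individual

    by_ind: dict[str, list[EggMassRecord]] = {}
    for rec in records:
        if rec.individual_id not in pedigree:
            raise ValueError(
                f"egg mass {rec.eggmass_id!r}: individual {rec.individual_id!r} "
                "not present in pedigree"
            )
        by_ind.setdefault(rec.individual_id, []).append(rec)

    rows = []
    for ind in pedigree.individuals:
        recs = by_ind.get(ind.id, [])
        diams = [d for r in recs for d in r.capsule_diams_um]
        mean_capsule = float(np.mean(diams)) if diams else np.nan
        if recs:
            calls = {classify_egg_mass(r.capsule_diams_um).mode for r in recs}
            mode = calls.pop() if len(calls) == 1 else "M"
            y = classify_individual(mean_capsule)
        else:
            mode, y = "", np.nan
        rows.append(
            {
                "individual_id": ind.id,
                "family": ind.family,
                "site": ind.site,
                "dish": ind.dish,
                "salinity": ind.salinity,
                "generation": ind.generation,
                "selfed": ind.selfed,
                "mean_capsule_um": mean_capsule,
                "y": y,
                "mode": mode,
                "n_eggmasses": len(recs),
            }
        )
    return PhenotypeTable(pd.DataFrame(rows))


def _parse_diams(cell: str, what: str, eggmass_id: str) -> tuple[float, ...]:
    vals = tuple(float(x) for x in str(cell).split(";") if str(x).strip() != "")
    for v in vals:
        if not v > 0:
            raise ValueError(
                f"egg mass {eggmass_id!r}: {what} diameter {v} is not positive"
            )
    return vals


def read_phenotypes(
    path: str | Path,
) -> tuple[Pedigree, PhenotypeTable, list[EggMassRecord]]:
    """Read a combined phenotype/pedigree CSV.

    Each row carries one egg mass together with the laying individual's
    pedigree links; rows with an empty ``capsule_diams`` cell declare an
    individual (e.g. a founder or a non-laying survivor) without a clutch.
    Unknown columns are ignored with a warning; missing required columns and
    malformed values are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in _PHENOTYPE_COLUMNS if c != "egg_diams"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"phenotypes file {path}: missing required column {col!r}")
    unknown = [c for c in df.columns if c not in _PHENOTYPE_COLUMNS]
    if unknown:
        _log.warning("ignoring unknown columns in %s: %s", path, unknown)

    individuals: list[Individual] = []
    seen: set[str] = set()
    records: list[EggMassRecord] = []
    for _, row in df.iterrows():
        iid = row["individual_id"]
        if iid not in seen:
            individuals.append(
                Individual(
                    id=iid,
                    family=row["family"],
                    site=row["site"],
                    dish=row["dish"],
                    salinity=row["salinity"],
                    generation=row["generation"],
                    dam=row["dam"] or None,
                    sire=row["sire"] or None,
                    selfed=row["selfed"] in ("1", "True", "true"),
                )
            )
            seen.add(iid)
        if str(row["capsule_diams"]).strip() == "":
            continue
        egg_cell = row.get("egg_diams", "")
        records.append(
            EggMassRecord(
                eggmass_id=row["eggmass_id"],
                individual_id=iid,
                order_index=int(row["order_index"]),
                capsule_diams_um=_parse_diams(
                    row["capsule_diams"], "capsule", row["eggmass_id"]
                ),
                egg_diams_um=(
                    _parse_diams(egg_cell, "egg", row["eggmass_id"])
                    if str(egg_cell).strip() != ""
                    else None
                ),
            )
        )
    pedigree = Pedigree(individuals)
    table = build_phenotype_table(pedigree, records)
    return pedigree, table, records


def _fmt(x: float) -> str:
    # fixed one-decimal µm formatting keeps the CSV bit-stable across writes
    return format(float(x), ".1f")


def write_phenotypes(
    path: str | Path,
    pedigree: Pedigree,
    records: Sequence[EggMassRecord],
) -> None:
    """Write the combined phenotype/pedigree CSV (fixed column order and
    float format so that write-read-write is byte identical)."""
    by_ind: dict[str, list[EggMassRecord]] = {}
    for rec in records:
        by_ind.setdefault(rec.individual_id, []).append(rec)

    lines = [",".join(_PHENOTYPE_COLUMNS)]
    for ind in pedigree.individuals:
        base = [
            ind.family,
            ind.site,
            ind.dish,
            ind.salinity,
            ind.generation,
            ind.dam or "",
            ind.sire or "",
            str(int(ind.selfed)),
        ]
        recs = sorted(by_ind.get(ind.id, []), key=lambda r: r.order_index)
        if not recs:
            lines.append(",".join(["", ind.id, *base, "", "", ""]))
        for rec in recs:
            lines.append(
                ",".join(
                    [
                        rec.eggmass_id,
                        ind.id,
                        *base,
                        str(rec.order_index),
                        ";".join(_fmt(d) for d in rec.capsule_diams_um),
                        (
                            ";".join(_fmt(d) for d in rec.egg_diams_um)
                            if rec.egg_diams_um is not None
                            else ""
                        ),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a bare ``id,dam,sire,selfed`` pedigree CSV (order-validated)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _PEDIGREE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"pedigree file {path}: missing required column {col!r}")
    seen: set[str] = set()
    for _, row in df.iterrows():
        for parent in (row["dam"], row["sire"]):
            if parent and parent not in seen:
                raise ValueError(
                    f"pedigree file {path}: parent {parent!r} of {row['id']!r} "
                    "not previously defined"
                )
        if row["id"] in seen:
            raise ValueError(f"pedigree file {path}: duplicate id {row['id']!r}")
        seen.add(row["id"])
    df["selfed"] = df["selfed"].isin(("1", "True", "true")).astype(int)
    return df[_PEDIGREE_COLUMNS]


def write_pedigree(path: str | Path, pedigree: Pedigree | pd.DataFrame) -> None:
    df = pedigree.to_frame() if isinstance(pedigree, Pedigree) else pedigree
    lines = [",".join(_PEDIGREE_COLUMNS)]
    for _, row in df.iterrows():
        lines.append(
            ",".join(
                [str(row["id"]), str(row["dam"]), str(row["sire"]), str(int(row["selfed"]))]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
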