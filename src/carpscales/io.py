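"""Tabular I/O: cross tables, per-fish records, distributions, scale maps.

All tables are plain CSV (comma, UTF-8, header row); reports and run
configuration are JSON.  A packaged fixture carries the 19 published crosses
with their printed observed percentages and expected-cell strings kept
verbatim for provenance (two linear x mirror rows are flagged where the
printed expected cells are inconsistent with Punnett arithmetic).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genetic_model import (
    OBSERVABLE_CATEGORIES,
    Phenotype,
    PhenotypeDistribution,
)
from .inference import ObservedCross, reconstruct_counts
from .phenotype_scoring import Fin, FinState, FishRecord

__all__ = [
    "load_cross_table",
    "write_cross_table",
    "table2_fixture",
    "load_fish_records",
    "write_fish_records",
    "distribution_to_csv",
    "distribution_to_json",
    "write_scale_map_pgm",
    "write_scale_map_csv",
    "RunConfig",
]

_COUNT_COLUMNS = [c.value for c in OBSERVABLE_CATEGORIES]


def _parse_parent_phenotypes(ph1: str, ph2: str) -> tuple[Phenotype, Phenotype]:
    aliases = {"irreg": "irregular", "irreg.": "irregular"}
    out = []
    for raw in (ph1, ph2):
        name = aliases.get(raw.strip().lower(), raw.strip().lower())
        try:
            out.append(Phenotype(name))
        except ValueError as exc:
            raise ValueError(f"unknown parent phenotype {raw!r}") from exc
    return out[0], out[1]


def load_cross_table(path: str | Path, mode: str = "counts") -> list[ObservedCross]:
    """Read a cross table CSV into validated :class:`ObservedCross` records.

    Expected columns: ``label, location, parent1_phenotype, parent2_phenotype,
    total_n`` plus one column per observed category.  ``mode`` selects whether
    category columns hold integer counts or printed percentages (the latter
    are converted through :func:`reconstruct_counts`).
    """
    if mode not in ("counts", "percentages"):
        raise ValueError("mode must be 'counts' or 'percentages'")
    path = Path(path)
    crosses: list[ObservedCross] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file, no crosses loaded", UserWarning)
            return []
        required = {"label", "parent1_phenotype", "parent2_phenotype", "total_n"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                crosses.append(_row_to_cross(row, mode))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    if not crosses:
        warnings.warn(f"{path}: no cross rows found", UserWarning)
    return crosses


def _row_to_cross(row: dict, mode: str) -> ObservedCross:
    parents = _parse_parent_phenotypes(
        row["parent1_phenotype"], row["parent2_phenotype"]
    )
    total_n = int(row["total_n"])
    raw = {
        cat: float(row[cat.value])
        for cat in OBSERVABLE_CATEGORIES
        if row.get(cat.value) not in (None, "")
    }
    if mode == "percentages":
        counts = reconstruct_counts(total_n, raw)
    else:
        counts = {}
        for cat, v in raw.items():
            if v != int(v):
                raise ValueError(f"non-integer count {v} for {cat.value}")
            counts[cat] = int(v)
    return ObservedCross(
        label=row["label"],
        parent_phenotypes=parents,
        total_n=total_n,
        counts=counts,
        location=row.get("location", ""),
    )


def write_cross_table(
    crosses: Sequence[ObservedCross], path: str | Path
) -> None:
    """Write crosses in the counts dialect read back by :func:`load_cross_table`."""
    path = Path(path)
    cols = [
        "label",
        "location",
        "parent1_phenotype",
        "parent2_phenotype",
        "total_n",
        *_COUNT_COLUMNS,
    ]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for x in crosses:
            row = {
                "label": x.label,
                "location": x.location,
                "parent1_phenotype": x.parent_phenotypes[0].value,
                "parent2_phenotype": x.parent_phenotypes[1].value,
                "total_n": x.total_n,
            }
            for cat in OBSERVABLE_CATEGORIES:
                row[cat.value] = x.counts.get(cat, 0)
            writer.writerow(row)


_EXPECTED_COLS = {
    Phenotype.SCALED: "expected_scaled",
    Phenotype.LINEAR: "expected_linear",
    Phenotype.SCATTERED: "expected_scattered",
    Phenotype.NUDE: "expected_nude",
    Phenotype.LETHAL: "expected_lethal",
}


def table2_fixture() -> list[ObservedCross]:
    """The 19 published crosses: labels, origins, total offspring and observed
    percentages (converted to counts), with the printed expected-percentage
    strings kept verbatim in each record's metadata."""
    ref = resources.files("carpscales").joinpath("data/table2.csv")
    crosses: list[ObservedCross] = []
    with ref.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ph1, ph2 = row["cross_type"].split(" x ")
            parents = _parse_parent_phenotypes(ph1, ph2)
            total_n = int(row["total_n"])
            percentages = {
                cat: float(row[f"obs_{cat.value}"])
                for cat in OBSERVABLE_CATEGORIES
                if row[f"obs_{cat.value}"] != ""
            }
            counts = reconstruct_counts(total_n, percentages)
            crosses.append(
                ObservedCross(
                    label=row["label"],
                    parent_phenotypes=parents,
                    total_n=total_n,
                    counts=counts,
                    location=row["location"],
                    metadata={
                        "no": int(row["no"]),
                        "alias": row["alias"] or None,
                        "cross_type": row["cross_type"],
                        "male_origin": row["male_origin"],
                        "female_origin": row["female_origin"],
                        "male_id": row["male_id"],
                        "female_id": row["female_id"],
                        "observed_percentages": {
                            cat.value: pct for cat, pct in percentages.items()
                        },
                        "expected_printed": {
                            cat.value: row[col]
                            for cat, col in _EXPECTED_COLS.items()
                            if row[col] != ""
                        },
                        "inconsistent_with_model": row["inconsistent_with_model"]
                        == "true",
                    },
                )
            )
    assert len(crosses) == 19
    return crosses


_FIN_COLS = [f.value for f in Fin]


def write_fish_records(fish: Sequence[FishRecord], path: str | Path) -> None:
    path = Path(path)
    cols = ["id", "family", "category", "nude_subtype", "teeth_count", *_FIN_COLS]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for f in fish:
            row = {
                "id": f.id,
                "family": f.family,
                "category": f.category.value,
                "nude_subtype": f.nude_subtype or "",
                "teeth_count": f.teeth_count,
            }
            for fin in Fin:
                row[fin.value] = f.fins[fin].value
            writer.writerow(row)


def load_fish_records(path: str | Path) -> list[FishRecord]:
    path = Path(path)
    out: list[FishRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file, no fish loaded", UserWarning)
            return []
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    FishRecord(
                        id=row["id"],
                        family=row["family"],
                        category=Phenotype(row["category"]),
                        fins={fin: FinState(row[fin.value]) for fin in Fin},
                        teeth_count=int(row["teeth_count"]),
                        nude_subtype=row.get("nude_subtype") or None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return out


def distribution_to_csv(dist: PhenotypeDistribution, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "probability"])
        for cat, p in dist.probabilities.items():
            writer.writerow([cat.value, float(p)])


def distribution_to_json(dist: PhenotypeDistribution) -> dict:
    return {
        "includes_lethal": dist.includes_lethal,
        "probabilities": {c.value: float(p) for c, p in dist.probabilities.items()},
        "percent": {c.value: float(p) * 100 for c, p in dist.probabilities.items()},
    }


def write_scale_map_pgm(scale_map: np.ndarray, path: str | Path) -> None:
    """Write a boolean scale map as a plain-text (P2) PGM image."""
    rows, cols = scale_map.shape
    lines = [f"P2", f"{cols} {rows}", "1"]
    for r in range(rows):
        lines.append(" ".join("1" if v else "0" for v in scale_map[r]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_scale_map_csv(scale_map: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, scale_map.astype(int), fmt="%d", delimiter=",")


@dataclass
class RunConfig:
    """Validated, persistable configuration of a pipeline run."""

    models: list[str] = field(default_factory=lambda: ["standard"])
    merge_scattered: bool = True
    count_mode: str = "counts"
    seed: int | None = None
    outdir: str | None = None
    rheostat: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .genetic_model import MODELS_BY_NAME

        for name in self.models:
            if name not in MODELS_BY_NAME:
                raise ValueError(f"unknown allele model {name!r}")
        if self.count_mode not in ("counts", "percentages"):
            raise ValueError("count_mode must be 'counts' or 'percentages'")

    def to_json(self, path: str | Path) -> None:
        from . import __version__

        payload = {"version": __version__, **dataclasses.asdict(self)}
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        data.pop("version", None)
        return cls(**data)
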