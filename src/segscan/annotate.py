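"""Metabolite annotation by mass tolerance against a compound table.

Picked peaks are matched to an HMDB-style table of monoisotopic masses via
polarity-appropriate adducts ([M+H]+ / [M-H]- by default, configurable)
within a mass tolerance of ±0.2 Da — the working tolerance of a unit-
resolution ion trap.  All candidates inside the tolerance are kept, ranked
by absolute mass error; compound-level deduplication happens when counting
identifications per sample.  A bundled table of ~170 common metabolites with
formula-derived monoisotopic masses ships with the package as a stand-in
for a database download.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CompoundRecord",
    "Identification",
    "DEFAULT_ADDUCTS",
    "PROTON_MASS",
    "load_compound_table",
    "match",
    "cross_polarity_union",
    "PolarityCounts",
]

#: proton mass, Da (electron mass neglected: ~5e-4 Da << 0.2 Da tolerance)
PROTON_MASS = 1.00728

DEFAULT_ADDUCTS: dict[str, dict[str, float]] = {
    "positive": {"[M+H]+": +PROTON_MASS},
    "negative": {"[M-H]-": -PROTON_MASS},
}


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    monoisotopic_mass: float
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic_mass must be positive")


@dataclass(frozen=True)
class Identification:
    peak_mz: float
    compound_id: str
    compound_name: str
    adduct: str
    mass_error: float
    polarity: str


def load_compound_table(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load a tab-delimited compound table (id, name, monoisotopic_mass, class).

    With no path, the bundled metabolite table is used.
    """
    if path is None:
        src = resources.files("segscan.data").joinpath("compounds.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"id", "name", "monoisotopic_mass"}
    if not required <= set(df.columns):
        raise ValueError(f"compound table needs columns {sorted(required)}")
    cls_col = "class" if "class" in df.columns else None
    return [
        CompoundRecord(
            id=str(r["id"]),
            name=str(r["name"]),
            monoisotopic_mass=float(r["monoisotopic_mass"]),
            class_label=str(r[cls_col]) if cls_col else "",
        )
        for _, r in df.iterrows()
    ]


def _peak_mz_polarity(peak) -> tuple[float, str]:
    if isinstance(peak, tuple):
        return float(peak[0]), str(peak[1])
    mz = getattr(peak, "picked_mz", None)
    if mz is None:
        mz = getattr(peak, "mz")
    return float(mz), str(getattr(peak, "polarity", "negative"))


def match(
    peaks: Iterable,
    table: Sequence[CompoundRecord],
    tolerance: float = 0.2,
    adducts_by_polarity: dict[str, dict[str, float]] | None = None,
) -> list[Identification]:
    """Match peaks against the table within ±``tolerance`` Da.

    ``peaks`` may be ``(mz, polarity)`` tuples or objects exposing
    ``picked_mz``/``mz`` and ``polarity`` (e.g. :class:`PeakMeasurement`).
    Every (peak, compound, adduct) combination whose expected adduct m/z lies
    within the tolerance is emitted; the result is sorted per peak by
    absolute mass error so the best candidate comes first.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    adducts = adducts_by_polarity or DEFAULT_ADDUCTS
    out: list[Identification] = []
    for peak in peaks:
        mz, pol = _peak_mz_polarity(peak)
        hits = []
        for rec in table:
            for adduct, delta in adducts.get(pol, {}).items():
                err = mz - (rec.monoisotopic_mass + delta)
                if abs(err) <= tolerance:
                    hits.append(
                        Identification(
                            peak_mz=mz,
                            compound_id=rec.id,
                            compound_name=rec.name,
                            adduct=adduct,
                            mass_error=err,
                            polarity=pol,
                        )
                    )
        hits.sort(key=lambda h: abs(h.mass_error))
        out.extend(hits)
    return out


PolarityCounts = namedtuple("PolarityCounts", "n_pos n_neg n_both n_union")


def cross_polarity_union(pos: set, neg: set) -> PolarityCounts:
    """Combine compound identifications across ionization polarities.

    Returns the positive-mode count, negative-mode count, the overlap, and
    the inclusion-exclusion union ``n_pos + n_neg - n_both``.
    """
    pos, neg = set(pos), set(neg)
    both = pos & neg
    return PolarityCounts(len(pos), len(neg), len(both), len(pos | neg))
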