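"""Tabular file formats, packaged datasets, and deterministic reports.

Everything is TSV (the counts in question are small printed tables), with
UTF-8, "." decimals and KI..KIV as canonical karyomorph labels.

Packaged fixtures (loaded with :func:`load_fixture`):

``sex_ratios``
    Sons / sexed offspring per dam karyomorph (54/149, 70/171, 7/7), 38
    dams, 327 offspring.
``karyotyped_daughters``
    Karyomorph counts of the 64 karyotyped daughters: KII dams 9:25:3,
    KIII dams 21:6:0 (KII:KIII:KIV).
``painted_individuals``
    The 12 animals resolved by chromosome painting (5 wild, 7 colony),
    with complement strings and the LMAN2 inversion type (2a/2b/2c) as
    metadata.
``reproductive_cohort``
    Cohort sizes of the reproductive-success experiment (13 KII, 15 KIII,
    4 KIV); breeder counts are recorded only where printed (0 of 4 KIV).
"""

from __future__ import annotations

import sys
from importlib import resources
from typing import Mapping

import pandas as pd

from .karyotype import Karyomorph
from .inference import CrossCounts, ProgenyCounts

__all__ = [
    "FIXTURES",
    "load_fixture",
    "observed_progeny_counts",
    "read_progeny_table",
    "write_progeny_table",
    "per_dam_to_progeny_table",
    "write_report",
    "ProgenyTableError",
]

FIXTURES = (
    "sex_ratios",
    "karyotyped_daughters",
    "painted_individuals",
    "reproductive_cohort",
)

_DAUGHTER_CLASSES = (Karyomorph.KII, Karyomorph.KIII, Karyomorph.KIV)

PROGENY_COLUMNS = [
    "dam_id",
    "dam_karyomorph",
    "sire_karyomorph",
    "n_sons",
    "n_daughters",
]
KARYOTYPED_COLUMNS = [f"k_daughters_{k.value}" for k in _DAUGHTER_CLASSES]


class ProgenyTableError(ValueError):
    """Progeny table parse/validation failure, with row location."""


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged dataset by name (see module docstring)."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        )
    ref = resources.files("neoxy.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def observed_progeny_counts() -> ProgenyCounts:
    """The observed colony data as :class:`~neoxy.inference.ProgenyCounts`
    (sex ratios pooled with the karyotyped-daughter subsample)."""
    ratios = load_fixture("sex_ratios").set_index("dam_karyomorph")
    daughters = load_fixture("karyotyped_daughters").set_index("dam_karyomorph")
    crosses = {}
    for label, row in ratios.iterrows():
        k = Karyomorph(label)
        karyotyped: dict[Karyomorph, int] = {}
        if label in daughters.index:
            drow = daughters.loc[label]
            karyotyped = {
                c: int(drow[f"daughters_{c.value}"]) for c in _DAUGHTER_CLASSES
            }
        crosses[k] = CrossCounts(
            n_dams=int(row["n_dams"]),
            n_sons=int(row["n_sons"]),
            n_daughters=int(row["n_offspring"]) - int(row["n_sons"]),
            karyotyped=karyotyped,
        )
    return ProgenyCounts(crosses=crosses)


def read_progeny_table(path) -> ProgenyCounts:
    """Read and validate a per-dam progeny TSV into pooled counts.

    Required columns: dam_id, dam_karyomorph, sire_karyomorph, n_sons,
    n_daughters; optional k_daughters_KII/KIII/KIV for the karyotyped
    subsample.  Validation failures name the offending row.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PROGENY_COLUMNS if c not in table.columns]
    if missing:
        raise ProgenyTableError(f"{path}: missing columns {missing}")
    has_k = all(c in table.columns for c in KARYOTYPED_COLUMNS)
    valid_dams = {k.value for k in _DAUGHTER_CLASSES}
    for idx, row in table.iterrows():
        line = idx + 2  # header is line 1
        if row["dam_karyomorph"] not in valid_dams:
            raise ProgenyTableError(
                f"{path}, line {line}: unknown dam karyomorph "
                f"{row['dam_karyomorph']!r} (expected KII/KIII/KIV)"
            )
        if row["sire_karyomorph"] != Karyomorph.KI.value:
            raise ProgenyTableError(
                f"{path}, line {line}: sire karyomorph must be KI, got "
                f"{row['sire_karyomorph']!r}"
            )
        for col in ["n_sons", "n_daughters", *(KARYOTYPED_COLUMNS if has_k else [])]:
            v = row[col]
            if pd.isna(v) or int(v) != v or int(v) < 0:
                raise ProgenyTableError(
                    f"{path}, line {line}: column {col} must be a "
                    f"non-negative integer, got {v!r}"
                )
        if has_k:
            k_sum = sum(int(row[c]) for c in KARYOTYPED_COLUMNS)
            if k_sum > int(row["n_daughters"]):
                raise ProgenyTableError(
                    f"{path}, line {line}: karyotyped daughters ({k_sum}) "
                    f"exceed n_daughters ({int(row['n_daughters'])})"
                )
    crosses = {}
    for label, group in table.groupby("dam_karyomorph"):
        karyotyped = (
            {
                c: int(group[f"k_daughters_{c.value}"].sum())
                for c in _DAUGHTER_CLASSES
            }
            if has_k
            else {}
        )
        crosses[Karyomorph(label)] = CrossCounts(
            n_dams=len(group),
            n_sons=int(group["n_sons"].sum()),
            n_daughters=int(group["n_daughters"].sum()),
            karyotyped=karyotyped,
        )
    return ProgenyCounts(crosses=crosses)


def per_dam_to_progeny_table(per_dam: pd.DataFrame) -> pd.DataFrame:
    """Reshape a simulator per-dam table (daughters_K* columns) to the
    progeny-TSV schema (n_daughters plus k_daughters_K* columns)."""
    out = per_dam.copy()
    d_cols = [f"daughters_{k.value}" for k in _DAUGHTER_CLASSES]
    out["n_daughters"] = out[d_cols].sum(axis=1)
    keep = PROGENY_COLUMNS + [
        c for c in KARYOTYPED_COLUMNS if c in out.columns
    ]
    return out[keep]


def write_progeny_table(table: pd.DataFrame, path) -> None:
    """Write a progeny table TSV (stable column order, no index)."""
    missing = [c for c in PROGENY_COLUMNS if c not in table.columns]
    if missing:
        raise ProgenyTableError(f"cannot write progeny table; missing {missing}")
    cols = PROGENY_COLUMNS + [c for c in KARYOTYPED_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


def write_report(
    results,
    path,
    fmt: str = "tsv",
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write an analysis result deterministically.

    ``results`` is a DataFrame (or mapping converted to a two-column
    table).  Metadata (parameters, seeds) goes into sorted ``# key: value``
    header lines; floats are fixed to 10 significant digits so identical
    inputs produce byte-identical files.
    """
    if fmt not in ("tsv", "text"):
        raise ValueError(f"unknown report format {fmt!r}")
    if isinstance(results, Mapping):
        results = pd.DataFrame(
            {"key": list(results), "value": list(results.values())}
        )
    header = "".join(
        f"# {key}: {value}\n" for key, value in sorted((metadata or {}).items())
    )
    if fmt == "tsv":
        body = results.to_csv(sep="\t", index=False, float_format="%.10g")
    else:
        body = (
            results.to_string(index=False, float_format=lambda v: f"{v:.10g}")
            + "\n"
            if len(results)
            else "(empty)\n"
        )
    if hasattr(path, "write"):
        path.write(header + body)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + body)


def log(message: str) -> None:
    """Run-parameter echo to stderr."""
    print(message, file=sys.stderr)
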