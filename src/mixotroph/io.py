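"""Domain types, table readers/writers and numeric-cell normalization.

Tables are carried as validated :class:`pandas.DataFrame` objects with fixed
schemas; the enums below are the controlled vocabularies for the categorical
columns.  Supplementary tables from isotope studies routinely use typographic
minus signs and thousands separators, so every numeric cell passes through a
normalization step before parsing — locale-independent by construction.

Schemas
-------
isotope CSV
    ``specimen_id, population, plot_id, category, delta13C, delta15N``
OTU counts TSV
    first column ``otu_id``, remaining columns one per sample (integer reads)
taxonomy TSV
    ``otu_id, family, genus, guild``
sample metadata CSV
    ``sample_id, individual_id, population, morph, organ``
trait CSV
    ``individual_id, morph, scape_height_mm, n_scapes, n_flowers, n_leaves,
    leaf_length_mm, leaf_width_mm, fv_fm``
"""

from __future__ import annotations

import json
import logging
import re
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mixotroph")

__all__ = [
    "Category",
    "Morph",
    "Organ",
    "Guild",
    "ParseError",
    "normalize_number",
    "parse_float",
    "parse_int",
    "read_isotope_table",
    "read_otu_table",
    "read_trait_table",
    "write_report",
    "read_report",
]


class Category(str, Enum):
    """Specimen category in the isotope design."""

    AUTO_REF = "AUTO_REF"            # autotrophic reference plant
    OP_RHIZOME = "OP_RHIZOME"        # focal orchid with coralloid rhizome
    OP_ROOTS = "OP_ROOTS"            # focal orchid without coralloid rhizome
    OP_PROTOCORM = "OP_PROTOCORM"    # fully mycoheterotrophic protocorm


class Morph(str, Enum):
    WITH_RHIZOME = "WITH_RHIZOME"
    WITHOUT_RHIZOME = "WITHOUT_RHIZOME"
    PROTOCORM = "PROTOCORM"


class Organ(str, Enum):
    ROOT = "ROOT"
    RHIZOME = "RHIZOME"
    WHOLE = "WHOLE"


class Guild(str, Enum):
    """Coarse trophic guild used to whitelist putative orchid mycorrhizae."""

    RHIZOCTONIA = "RHIZOCTONIA"
    SAPROTROPH_NONRHIZOCTONIA = "SAPROTROPH_NONRHIZOCTONIA"
    ECM = "ECM"
    OTHER_ORCHID_MYC = "OTHER_ORCHID_MYC"
    NON_MYCORRHIZAL = "NON_MYCORRHIZAL"


class ParseError(ValueError):
    """A table cell or row violated the declared schema."""


# U+2212 minus and the U+2010..2015 dash family -> ASCII hyphen-minus
_MINUS_RE = re.compile("[\u2212\u2010-\u2015]")
# thousands separators: comma, regular/no-break/thin/narrow spaces
_SEP_RE = re.compile("[,\u0020\u00a0\u2009\u202f]")
_MISSING = {"", "na", "nan", "n/a", "none", "."}


def normalize_number(cell: object) -> str | None:
    """Canonicalize a numeric cell: unify minus signs, strip separators.

    Returns ``None`` for missing values ("", "NA", "NaN", ...).
    """
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.lower() in _MISSING:
        return None
    text = _MINUS_RE.sub("-", text)
    return _SEP_RE.sub("", text)


def parse_float(cell: object, *, context: str = "") -> float:
    """Parse a real-valued cell; missing becomes NaN, junk raises ParseError."""
    text = normalize_number(cell)
    if text is None:
        return float("nan")
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"cannot parse {cell!r} as a number {context}".strip()) from None


def parse_int(cell: object, *, context: str = "") -> int:
    """Parse a non-negative integer cell (read counts); no missing allowed."""
    text = normalize_number(cell)
    if text is None:
        raise ParseError(f"missing value where an integer count is required {context}".strip())
    try:
        value = int(text)
    except ValueError:
        raise ParseError(f"cannot parse {cell!r} as an integer {context}".strip()) from None
    if value < 0:
        raise ParseError(f"negative count {value} {context}".strip())
    return value


def _map_enum(label: object, enum: type[Enum], mapping: Mapping[str, Enum] | None,
              *, row: object, column: str) -> Enum:
    """Map a text label to an enum member, via an optional user mapping."""
    text = str(label).strip()
    if mapping is not None and text in mapping:
        return mapping[text]
    try:
        return enum(text)
    except ValueError:
        allowed = sorted({m.value for m in enum} | (set(mapping) if mapping else set()))
        raise ParseError(
            f"unknown {column} label {text!r} in row {row!r}; allowed: {allowed}"
        ) from None


def read_isotope_table(path: str | Path,
                       category_labels: Mapping[str, Category] | None = None,
                       ) -> pd.DataFrame:
    """Read a per-specimen isotope CSV.

    Parameters
    ----------
    path
        CSV with columns ``specimen_id, population, plot_id, category,
        delta13C, delta15N``.  Delta values are per mil (‰); empty/``NA``
        cells become NaN (never zero).
    category_labels
        Optional mapping from file labels to :class:`Category`, so
        supplementary files with their own vocabulary can be ingested
        without editing code.

    Returns
    -------
    DataFrame with the schema above, ``category`` as string enum values.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["specimen_id", "population", "plot_id", "category", "delta13C", "delta15N"]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ParseError(f"isotope table {path} lacks columns {missing_cols}")

    records = []
    for _, row in raw.iterrows():
        sid = row["specimen_id"].strip()
        plot = row["plot_id"].strip()
        if not plot:
            raise ParseError(f"empty plot_id for specimen {sid!r}")
        cat = _map_enum(row["category"], Category, category_labels, row=sid, column="category")
        d13 = parse_float(row["delta13C"], context=f"(delta13C, specimen {sid})")
        d15 = parse_float(row["delta15N"], context=f"(delta15N, specimen {sid})")
        if np.isnan(d13) and np.isnan(d15):
            raise ParseError(f"specimen {sid!r} has neither delta13C nor delta15N")
        records.append((sid, row["population"].strip(), plot, cat.value, d13, d15))

    frame = pd.DataFrame(records, columns=required)
    dup = frame["specimen_id"][frame["specimen_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"duplicate specimen_id values: {sorted(dup.unique())}")
    logger.info("read_isotope_table: %d rows in, %d specimens out", len(raw), len(frame))
    return frame


def read_otu_table(counts_path: str | Path,
                   taxonomy_path: str | Path,
                   meta_path: str | Path,
                   morph_labels: Mapping[str, Morph] | None = None,
                   organ_labels: Mapping[str, Organ] | None = None,
                   guild_labels: Mapping[str, Guild] | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an OTU read-count TSV plus taxonomy TSV and sample-metadata CSV.

    Returns ``(otus, meta)``:

    * ``otus`` — one row per OTU: ``otu_id, family, genus, guild`` then one
      integer column per sample (thousands separators stripped);
    * ``meta`` — ``sample_id, individual_id, population, morph, organ``.

    Every sample column must appear in the metadata and every OTU in the
    taxonomy; violations raise :class:`ParseError` naming the offender.
    """
    counts = pd.read_csv(counts_path, sep="\t", dtype=str, keep_default_na=False)
    if counts.columns[0] != "otu_id":
        raise ParseError(f"first column of {counts_path} must be 'otu_id'")
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
    meta_raw = pd.read_csv(meta_path, dtype=str, keep_default_na=False)

    sample_ids = list(counts.columns[1:])
    meta_records = []
    for _, row in meta_raw.iterrows():
        morph = _map_enum(row["morph"], Morph, morph_labels, row=row["sample_id"], column="morph")
        organ = _map_enum(row["organ"], Organ, organ_labels, row=row["sample_id"], column="organ")
        if morph is Morph.PROTOCORM and organ is not Organ.WHOLE:
            raise ParseError(f"protocorm sample {row['sample_id']!r} must have organ WHOLE")
        meta_records.append((row["sample_id"].strip(), row["individual_id"].strip(),
                             row["population"].strip(), morph.value, organ.value))
    meta = pd.DataFrame(meta_records, columns=["sample_id", "individual_id",
                                               "population", "morph", "organ"])
    if meta["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in metadata")

    known = set(meta["sample_id"])
    orphans = [s for s in sample_ids if s not in known]
    if orphans:
        raise ParseError(f"samples in counts absent from metadata: {orphans}")

    tax_by_otu = tax.set_index("otu_id")
    records = []
    for _, row in counts.iterrows():
        otu = row["otu_id"].strip()
        if otu not in tax_by_otu.index:
            raise ParseError(f"OTU {otu!r} missing from taxonomy table")
        trow = tax_by_otu.loc[otu]
        guild = _map_enum(trow["guild"], Guild, guild_labels, row=otu, column="guild")
        rec = {"otu_id": otu, "family": trow["family"].strip(),
               "genus": trow.get("genus", "").strip(), "guild": guild.value}
        for s in sample_ids:
            rec[s] = parse_int(row[s], context=f"(OTU {otu}, sample {s})")
        records.append(rec)

    otus = pd.DataFrame(records)
    if otus["otu_id"].duplicated().any():
        raise ParseError("duplicate otu_id in counts table")
    logger.info("read_otu_table: %d OTUs x %d samples", len(otus), len(sample_ids))
    return otus, meta


def read_trait_table(path: str | Path,
                     morph_labels: Mapping[str, Morph] | None = None) -> pd.DataFrame:
    """Read a per-individual phenotype CSV (scape, flower, leaf, Fv/Fm traits)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    real_cols = ["scape_height_mm", "leaf_length_mm", "leaf_width_mm", "fv_fm"]
    int_cols = ["n_scapes", "n_flowers", "n_leaves"]
    records = []
    for _, row in raw.iterrows():
        morph = _map_enum(row["morph"], Morph, morph_labels,
                          row=row["individual_id"], column="morph")
        rec = {"individual_id": row["individual_id"].strip(), "morph": morph.value}
        for c in real_cols:
            rec[c] = parse_float(row[c], context=f"({c}, {rec['individual_id']})")
        for c in int_cols:
            rec[c] = parse_int(row[c], context=f"({c}, {rec['individual_id']})")
        if not np.isnan(rec["fv_fm"]) and not 0.0 <= rec["fv_fm"] <= 1.0:
            raise ParseError(f"fv_fm {rec['fv_fm']} outside [0, 1] "
                             f"for {rec['individual_id']!r}")
        records.append(rec)
    frame = pd.DataFrame(records)
    logger.info("read_trait_table: %d individuals", len(frame))
    return frame


def write_report(results: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a result table with deterministic column/key order.

    ``tsv`` writes tab-separated text with a header (17 significant digits so
    a round trip reproduces floats bit-exactly); ``json`` writes a list of
    row objects in column order.
    """
    if results is None:
        raise ValueError("results must not be None")
    path = Path(path)
    if format == "tsv":
        results.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "json":
        payload = results.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1, default=str) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    logger.info("write_report: %d rows -> %s (%s)", len(results), path, format)


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a table written by :func:`write_report`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise ValueError(f"unknown report format {format!r}")
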