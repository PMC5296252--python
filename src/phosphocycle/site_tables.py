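"""Phosphosite quantification tables and sequence-window extraction.

Site-level tables are TSV files with one row per quantified phosphosite,
carrying per-mixture heavy/light SILAC ratios and per-timepoint intensities.
Two header dialects are understood: the package's own simulator schema and a
MaxQuant Phospho(STY)Sites-like schema, so externally produced site tables can
be ingested without conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PAD_CHAR = "_"
WINDOW_FLANK = 6
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1


class SchemaError(ValueError):
    """A required column is absent from a site table."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""


@dataclass
class PhosphositeRecord:
    """One quantified phosphosite.

    ``ratios`` maps mixture identifiers to positive heavy/light ratios;
    ``intensities`` maps timepoints (minutes) to non-negative values.
    Missing measurements are simply absent from the maps.
    """

    site_id: str
    protein_id: str
    position: int
    acceptor: str
    window: str
    localization_probability: float = 1.0
    ratios: dict = field(default_factory=dict)
    intensities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise ValueError(
                f"window must be {WINDOW_LENGTH} residues, got {len(self.window)}"
            )
        if self.window[WINDOW_FLANK] != self.acceptor:
            raise ValueError(
                f"window center {self.window[WINDOW_FLANK]!r} does not match "
                f"acceptor {self.acceptor!r}"
            )
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError("localization_probability must be in [0, 1]")
        for mid, r in self.ratios.items():
            if not r > 0:
                raise ValueError(f"ratio for mixture {mid!r} must be > 0, got {r}")


def extract_window(sequence: str, position: int, flank: int = WINDOW_FLANK) -> str:
    """Return the ``2*flank+1``-mer centred on 1-based ``position``.

    Positions hanging over the sequence ends are padded with ``_`` (the
    MaxQuant convention), so the centre residue is always at index ``flank``.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    i = position - 1
    left = sequence[max(0, i - flank) : i]
    right = sequence[i + 1 : i + 1 + flank]
    return (
        PAD_CHAR * (flank - len(left))
        + left
        + sequence[i]
        + right
        + PAD_CHAR * (flank - len(right))
    )


# Column names of the native simulator schema.
_NATIVE_REQUIRED = ["site_id", "protein_id", "position", "amino_acid", "sequence_window"]
_NATIVE_LOCPROB = "localization_prob"
RATIO_PREFIX = "ratio_HL."
INTENSITY_PREFIX = "intensity.t"

# MaxQuant Phospho(STY)Sites-like schema.
_MAXQUANT_MAP = {
    "Protein": "protein_id",
    "Position": "position",
    "Amino acid": "amino_acid",
    "Sequence window": "sequence_window",
}
_MAXQUANT_LOCPROB = "Localization prob"
_MAXQUANT_RATIO_PREFIX = "Ratio H/L normalized "
_MAXQUANT_MARKER_COLUMNS = ("Reverse", "Potential contaminant")

DIALECTS = ("native", "maxquant")


def _parse_cell(value, row_index: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NaN", "nan", "NA"):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ParseError(
            f"row {row_index}: non-numeric value {value!r} in column {column!r}"
        ) from exc


def read_site_table(
    path,
    dialect: str = "native",
    min_localization_probability: float | None = None,
) -> list[PhosphositeRecord]:
    """Read a TSV phosphosite table into a list of records.

    Rows flagged as decoy hits (``Reverse`` == '+') or contaminants are
    dropped when those marker columns exist. Empty/NaN cells become missing
    measurements. ``min_localization_probability`` optionally filters sites
    by localization confidence (off by default).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")

    if dialect == "maxquant":
        for marker in _MAXQUANT_MARKER_COLUMNS:
            if marker in df.columns:
                df = df[df[marker].fillna("") != "+"]
        missing = [c for c in _MAXQUANT_MAP if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = df.rename(columns=_MAXQUANT_MAP)
        locprob_col = _MAXQUANT_LOCPROB
        ratio_prefix = _MAXQUANT_RATIO_PREFIX
        if "site_id" not in df.columns:
            df["site_id"] = df["protein_id"] + "_" + df["position"]
    else:
        missing = [c for c in _NATIVE_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        locprob_col = _NATIVE_LOCPROB
        ratio_prefix = RATIO_PREFIX

    ratio_cols = [c for c in df.columns if c.startswith(ratio_prefix)]
    intensity_cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)]

    records: list[PhosphositeRecord] = []
    for row_index, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        locprob = _parse_cell(row.get(locprob_col), row_index, locprob_col)
        locprob = 1.0 if locprob is None else locprob
        if (
            min_localization_probability is not None
            and locprob < min_localization_probability
        ):
            continue
        ratios = {}
        for col in ratio_cols:
            value = _parse_cell(row[col], row_index, col)
            if value is not None:
                ratios[col[len(ratio_prefix) :]] = value
        intensities = {}
        for col in intensity_cols:
            value = _parse_cell(row[col], row_index, col)
            if value is not None:
                intensities[int(col[len(INTENSITY_PREFIX) :])] = value
        records.append(
            PhosphositeRecord(
                site_id=str(row["site_id"]),
                protein_id=str(row["protein_id"]),
                position=int(row["position"]),
                acceptor=str(row["amino_acid"]),
                window=str(row["sequence_window"]),
                localization_probability=locprob,
                ratios=ratios,
                intensities=intensities,
            )
        )
    return records


def write_site_table(records: Iterable[PhosphositeRecord], path) -> None:
    """Write records as a native-dialect TSV; round-trips with read_site_table.

    The ratio/intensity column universe is the union over records; cells for
    measurements a record lacks are left blank.
    """
    records = list(records)
    mixture_ids = sorted({m for r in records for m in r.ratios})
    timepoints = sorted({t for r in records for t in r.intensities})
    columns = (
        _NATIVE_REQUIRED
        + [_NATIVE_LOCPROB]
        + [RATIO_PREFIX + m for m in mixture_ids]
        + [f"{INTENSITY_PREFIX}{t}" for t in timepoints]
    )
    rows = []
    for r in records:
        row = {
            "site_id": r.site_id,
            "protein_id": r.protein_id,
            "position": r.position,
            "amino_acid": r.acceptor,
            "sequence_window": r.window,
            _NATIVE_LOCPROB: r.localization_probability,
        }
        for m in mixture_ids:
            row[RATIO_PREFIX + m] = r.ratios.get(m, "")
        for t in timepoints:
            row[f"{INTENSITY_PREFIX}{t}"] = r.intensities.get(t, "")
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[PhosphositeRecord]) -> pd.DataFrame:
    """Wide DataFrame view (one row per site) of a list of records."""
    rows = []
    for r in records:
        row = {
            "site_id": r.site_id,
            "protein_id": r.protein_id,
            "position": r.position,
            "amino_acid": r.acceptor,
            "sequence_window": r.window,
            "localization_prob": r.localization_probability,
        }
        for m, v in r.ratios.items():
            row[RATIO_PREFIX + m] = v
        for t, v in r.intensities.items():
            row[f"{INTENSITY_PREFIX}{t}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id", drop=False)


def read_fasta(path) -> dict[str, str]:
    """Protein id -> sequence for a standard (wrapped or unwrapped) FASTA."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()),
        str(path),
        "fasta",
    )
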