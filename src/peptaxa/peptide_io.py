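"""Peptide-level search-result I/O and observation filtering.

Consumes the peptide table produced by a bottom-up metaproteomic database
search — MaxQuant's ``peptides.txt`` dialect or a generic TSV — in which each
identified peptide sequence carries a semicolon-separated protein group,
per-sample intensities, and decoy/contaminant flags.  Downstream annotation
is peptide-centric, so this is the pipeline's single entry point for
search-engine output.

Peptides whose protein group mixes microbial and host proteins are classed
``ambiguous`` and excluded from both microbial profiling and the
microbe/host ratio, avoiding double counting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "PeptideObservation",
    "read_peptides",
    "write_peptides",
    "filter_observations",
    "classify_origin",
]

logger = logging.getLogger(__name__)

_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")

OriginClass = Literal["microbial", "host", "ambiguous"]


class PeptideTableError(ValueError):
    """Raised for malformed peptide tables."""


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide: sequence, protein group, intensities, flags."""

    sequence: str
    protein_group: tuple[str, ...]
    intensities: dict[str, float] = field(default_factory=dict)
    is_decoy: bool = False
    is_contaminant: bool = False
    origin_class: OriginClass | None = None

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            # modification annotations / whitespace are rejected, not stripped
            raise PeptideTableError(
                f"invalid peptide sequence {self.sequence!r}: expected plain "
                "uppercase residues"
            )
        if not self.protein_group:
            raise PeptideTableError(
                f"peptide {self.sequence!r} has an empty protein group"
            )
        if any(v < 0 for v in self.intensities.values()):
            raise PeptideTableError(
                f"peptide {self.sequence!r} has a negative intensity"
            )

    def intensity(self, sample: str) -> float:
        """Intensity in ``sample``; absent samples quantify as 0."""
        return self.intensities.get(sample, 0.0)


def _parse_intensity(value: object, row: int, column: str) -> float:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return 0.0
    if isinstance(value, str) and not value.strip():
        return 0.0
    try:
        return float(value)
    except (TypeError, ValueError):
        raise PeptideTableError(
            f"non-numeric intensity {value!r} in column {column!r}, row {row}"
        ) from None


def read_peptides(
    path: str | Path, dialect: Literal["maxquant", "generic"] = "maxquant"
) -> list[PeptideObservation]:
    """Read a peptide table.

    ``maxquant``: tab-separated with columns ``Sequence``, ``Proteins`` and
    per-sample ``Intensity <sample>`` columns (or a lone ``Intensity``, in
    which case the single sample is named ``Intensity``); optional
    ``Reverse`` / ``Potential contaminant`` columns flag rows with ``+``.

    ``generic``: columns ``sequence``, ``proteins``, ``intensity_<sample>``…,
    optional boolean ``is_decoy`` / ``is_contaminant``.

    Rows with an empty protein group are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "maxquant":
        seq_col, prot_col = "Sequence", "Proteins"
        per_sample = {
            c: c[len("Intensity "):] for c in df.columns if c.startswith("Intensity ")
        }
        if not per_sample and "Intensity" in df.columns:
            per_sample = {"Intensity": "Intensity"}
        decoy_col, contam_col = "Reverse", "Potential contaminant"
        flag = lambda v: v.strip() == "+"  # noqa: E731
    elif dialect == "generic":
        seq_col, prot_col = "sequence", "proteins"
        per_sample = {
            c: c[len("intensity_"):] for c in df.columns if c.startswith("intensity_")
        }
        decoy_col, contam_col = "is_decoy", "is_contaminant"
        flag = lambda v: v.strip().lower() in {"1", "true", "+"}  # noqa: E731
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in (seq_col, prot_col):
        if col not in df.columns:
            raise PeptideTableError(f"required column: {col}")
    if not per_sample:
        raise PeptideTableError("required column: at least one intensity column")

    observations: list[PeptideObservation] = []
    dropped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        proteins = tuple(p for p in row[prot_col].split(";") if p)
        if not proteins:
            dropped += 1
            continue
        intensities = {
            sample: _parse_intensity(row[col], idx, col)
            for col, sample in per_sample.items()
        }
        observations.append(
            PeptideObservation(
                sequence=row[seq_col],
                protein_group=proteins,
                intensities=intensities,
                is_decoy=flag(row.get(decoy_col, "")),
                is_contaminant=flag(row.get(contam_col, "")),
            )
        )
    if dropped:
        logger.info("dropped %d rows with an empty protein group", dropped)
    return observations


def write_peptides(
    observations: Iterable[PeptideObservation], path: str | Path
) -> Path:
    """Write observations as a generic-dialect TSV (lossless round-trip)."""
    observations = list(observations)
    samples = sorted({s for ob in observations for s in ob.intensities})
    rows = []
    for ob in observations:
        row: dict[str, object] = {
            "sequence": ob.sequence,
            "proteins": ";".join(ob.protein_group),
            "is_decoy": int(ob.is_decoy),
            "is_contaminant": int(ob.is_contaminant),
        }
        for s in samples:
            row[f"intensity_{s}"] = repr(ob.intensity(s))
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def filter_observations(
    observations: Sequence[PeptideObservation],
) -> tuple[list[PeptideObservation], int, int]:
    """Drop decoy and contaminant rows.

    Returns ``(retained, n_decoys_removed, n_contaminants_removed)``;
    surviving rows are passed through unchanged.  A decoy that is also
    flagged contaminant counts once, as a decoy.
    """
    kept: list[PeptideObservation] = []
    n_decoy = n_contam = 0
    for ob in observations:
        if ob.is_decoy:
            n_decoy += 1
        elif ob.is_contaminant:
            n_contam += 1
        else:
            kept.append(ob)
    return kept, n_decoy, n_contam


def classify_origin(
    observations: Sequence[PeptideObservation],
    microbial_ids: set[str],
    host_ids: set[str],
) -> list[PeptideObservation]:
    """Set each observation's origin class from its protein group.

    All-microbial groups → ``microbial``; all-host → ``host``; mixed →
    ``ambiguous``.  Protein IDs in neither set are an error listing them.
    """
    out: list[PeptideObservation] = []
    unknown: set[str] = set()
    for ob in observations:
        in_microbe = any(p in microbial_ids for p in ob.protein_group)
        in_host = any(p in host_ids for p in ob.protein_group)
        unknown.update(
            p for p in ob.protein_group
            if p not in microbial_ids and p not in host_ids
        )
        if in_microbe and in_host:
            cls: OriginClass = "ambiguous"
        elif in_host:
            cls = "host"
        else:
            cls = "microbial"
        out.append(replace(ob, origin_class=cls))
    if unknown:
        shown = ", ".join(sorted(unknown)[:10])
        raise PeptideTableError(
            f"protein ids in neither the microbial nor the host set: {shown}"
        )
    return out
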