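"""Alignment and metadata I/O, sequence normalisation, geographic grouping.

The package works on fixed-length mitochondrial COI barcode alignments.
Sequences are stored as integer-coded matrices; terminal runs of ``N`` or
``-`` are treated as *missing* data (sequencing-length artefacts of the
barcode pipeline), while internal ``-`` is kept as a fifth character state.

Samples are binned into six broad geographic groups commonly used for
John Dory (*Zeus faber*) phylogeography: Northeast Atlantic (NEA),
Mediterranean (MED), Atlantic Africa (AFR), South Africa / Indian Ocean
(SA), Australia and New Zealand (AUS) and Asia (ASI).  Moroccan Atlantic
samples straddle the NEA/AFR boundary and are split by latitude at Cape
Boujdour (26.13° N).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "GeoGroup",
    "SampleMetadata",
    "SequenceRecord",
    "Alignment",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "assign_geographic_group",
    "variable_sites",
]

# Integer codes for the five character states plus the missing symbol.
A, C, G, T, GAP, MISSING = 0, 1, 2, 3, 4, 5
_CODE = {"A": A, "C": C, "G": G, "T": T, "-": GAP, "N": MISSING}
_CHAR = np.array(list("ACGT-N"))

#: Latitude of Cape Boujdour, the NEA/AFR boundary on the Moroccan coast.
CAPE_BOUJDOUR_LAT = 26.13


class AlignmentError(ValueError):
    """Malformed alignment input (shape, symbols, emptiness)."""


class GeoGroup(str, Enum):
    """The six geographic groups, plus UNASSIGNED for unresolvable samples."""

    NEA = "NEA"
    MED = "MED"
    AFR = "AFR"
    SA = "SA"
    AUS = "AUS"
    ASI = "ASI"
    UNASSIGNED = "UNASSIGNED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SampleMetadata:
    id: str
    country: str = ""
    region: str = ""
    latitude: float | None = None
    longitude: float | None = None
    group_override: GeoGroup | None = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range for {self.id!r}: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range for {self.id!r}: {self.longitude}")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its observed (non-missing) span."""

    id: str
    bases: str
    first_observed: int
    last_observed: int

    def __len__(self) -> int:
        return len(self.bases)


class Alignment:
    """A fixed-length nucleotide alignment with per-sample metadata.

    Internally a ``(N, L)`` uint8 matrix over the codes A=0, C=1, G=2, T=3,
    ``-``=4, missing=5.  Terminal ``N``/``-`` runs are recoded to the
    missing code at construction.
    """

    def __init__(
        self,
        ids: Sequence[str],
        matrix: np.ndarray,
        metadata: Mapping[str, SampleMetadata] | None = None,
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[0] == 0:
            raise AlignmentError("alignment must contain at least one sequence")
        if len(ids) != matrix.shape[0]:
            raise AlignmentError("ids and matrix row count differ")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if list(ids).count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        self.ids: list[str] = list(ids)
        self.matrix = matrix
        self.metadata: dict[str, SampleMetadata] = dict(metadata or {})
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Alignment N={self.n} L={self.length}>"

    def index_of(self, sid: str) -> int:
        return self._index[sid]

    # -- derived views -----------------------------------------------------
    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (N, L) mask of missing cells."""
        return self.matrix == MISSING

    def is_complete(self) -> bool:
        return not bool(self.missing_mask.any())

    def observed_span(self, i: int) -> tuple[int, int]:
        """(first, last) indices of the non-missing span of row ``i``."""
        obs = np.flatnonzero(self.matrix[i] != MISSING)
        if obs.size == 0:
            return (-1, -1)
        return int(obs[0]), int(obs[-1])

    @property
    def records(self) -> list[SequenceRecord]:
        out = []
        for i, sid in enumerate(self.ids):
            first, last = self.observed_span(i)
            out.append(
                SequenceRecord(
                    id=sid,
                    bases=row_to_string(self.matrix[i]),
                    first_observed=first,
                    last_observed=last,
                )
            )
        return out

    def sequence(self, sid: str) -> str:
        return row_to_string(self.matrix[self.index_of(sid)])

    def subset(self, ids: Iterable[str]) -> "Alignment":
        ids = list(ids)
        rows = [self.index_of(i) for i in ids]
        meta = {i: self.metadata[i] for i in ids if i in self.metadata}
        return Alignment(ids, self.matrix[rows].copy(), meta)

    def with_metadata(self, metadata: Mapping[str, SampleMetadata]) -> "Alignment":
        return Alignment(self.ids, self.matrix.copy(), metadata)

    def groups(self) -> dict[str, GeoGroup]:
        """Per-sample geographic group (override-aware); UNASSIGNED if no metadata."""
        out = {}
        for sid in self.ids:
            meta = self.metadata.get(sid)
            out[sid] = assign_geographic_group(meta) if meta else GeoGroup.UNASSIGNED
        return out


def row_to_string(row: np.ndarray) -> str:
    """Decode a coded row back to an ``ACGT-N`` string."""
    return "".join(_CHAR[row])


def encode_sequence(seq: str, *, record_id: str = "?") -> np.ndarray:
    """Encode an upper-cased sequence string, flagging terminal runs as missing."""
    seq = seq.upper()
    try:
        codes = np.array([_CODE[ch] for ch in seq], dtype=np.uint8)
    except KeyError as exc:
        col = next(i for i, ch in enumerate(seq) if ch not in _CODE)
        raise AlignmentError(
            f"non-IUPAC symbol {seq[col]!r} in record {record_id!r} at column {col}"
            " (only A/C/G/T/N/- are accepted)"
        ) from exc
    # terminal N or '-' runs are missing data
    present = (codes != GAP) & (codes != MISSING)
    obs = np.flatnonzero(present)
    if obs.size:
        codes[: obs[0]] = MISSING
        codes[obs[-1] + 1 :] = MISSING
    else:
        codes[:] = MISSING
    return codes


def read_alignment(
    path: str | Path, metadata: Mapping[str, SampleMetadata] | None = None
) -> Alignment:
    """Read a FASTA alignment; all sequences must share one length.

    Terminal ``N``/``-`` runs become missing spans; internal gaps are kept.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(
            f"sequences have unequal lengths {sorted(lengths)} in {path}"
        )
    rows = [encode_sequence(str(r.seq), record_id=r.id) for r in records]
    return Alignment(ids, np.vstack(rows), metadata)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write FASTA wrapped at 80 columns; missing cells are written as ``N``."""
    recs = [
        _BioSeqRecord(Seq(row_to_string(aln.matrix[i])), id=sid, description="")
        for i, sid in enumerate(aln.ids)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


# -- metadata ---------------------------------------------------------------

_META_COLUMNS = ["id", "country", "region", "latitude", "longitude", "group_override"]


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read the tab-separated metadata table (empty cells allowed)."""
    out: dict[str, SampleMetadata] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_META_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"metadata file {path} lacks columns: {sorted(missing)}")
        for row in reader:
            sid = row["id"].strip()
            override = row.get("group_override", "").strip()
            out[sid] = SampleMetadata(
                id=sid,
                country=row.get("country", "").strip(),
                region=row.get("region", "").strip(),
                latitude=float(row["latitude"]) if row.get("latitude", "").strip() else None,
                longitude=float(row["longitude"]) if row.get("longitude", "").strip() else None,
                group_override=GeoGroup(override) if override else None,
            )
    return out


def write_metadata(metadata: Mapping[str, SampleMetadata], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_META_COLUMNS)
        for meta in metadata.values():
            writer.writerow(
                [
                    meta.id,
                    meta.country,
                    meta.region,
                    "" if meta.latitude is None else repr(meta.latitude),
                    "" if meta.longitude is None else repr(meta.longitude),
                    "" if meta.group_override is None else meta.group_override.value,
                ]
            )


# -- geographic grouping ----------------------------------------------------

_NEA_COUNTRIES = {
    "portugal", "spain", "united kingdom", "uk", "great britain", "england",
    "scotland", "wales", "ireland", "germany", "denmark", "norway", "sweden",
    "netherlands", "belgium", "iceland", "faroe islands",
}
_MED_COUNTRIES = {
    "france", "greece", "israel", "italy", "malta", "turkey", "türkiye",
    "croatia", "cyprus", "albania", "montenegro", "slovenia", "tunisia",
    "algeria", "lebanon", "egypt", "libya", "syria",
}
_AFR_COUNTRIES = {
    "angola", "benin", "cote d'ivoire", "côte d'ivoire", "ivory coast",
    "liberia", "guinea-bissau", "guinea bissau", "guinea", "senegal",
    "mauritania", "ghana", "nigeria", "togo", "cameroon", "gabon", "congo",
    "namibia", "sierra leone", "gambia", "cape verde", "western sahara",
}
_AUS_COUNTRIES = {"australia", "new zealand"}
_ASI_COUNTRIES = {"japan", "china", "taiwan", "philippines", "south korea", "korea"}

_MED_SEAS = (
    "mediterranean", "adriatic", "aegean", "tyrrhenian", "ionian",
    "ligurian", "alboran", "levantine", "balearic",
)


def assign_geographic_group(meta: SampleMetadata | None) -> GeoGroup:
    """Map sample metadata to one of the six geographic groups.

    An explicit ``group_override`` always wins.  Moroccan Atlantic samples
    are split by latitude at Cape Boujdour (26.13° N): at or north of it they
    join the Northeast Atlantic, south of it Atlantic Africa.  Samples that
    cannot be resolved (no country, Mid-Atlantic Bight annotations, Moroccan
    Atlantic samples with no north/south information) fall back to
    UNASSIGNED and are excluded from group-wise statistics downstream.
    """
    if meta is None:
        return GeoGroup.UNASSIGNED
    if meta.group_override is not None:
        return meta.group_override

    country = meta.country.strip().lower()
    region = meta.region.strip().lower()

    if "mid-atlantic bight" in region or "mid atlantic bight" in region:
        return GeoGroup.UNASSIGNED

    if any(sea in region for sea in _MED_SEAS) and country != "morocco":
        return GeoGroup.MED

    if country == "morocco":
        if any(sea in region for sea in _MED_SEAS):
            return GeoGroup.MED
        if meta.latitude is not None:
            return GeoGroup.NEA if meta.latitude >= CAPE_BOUJDOUR_LAT else GeoGroup.AFR
        if "south" in region:
            return GeoGroup.AFR
        if "north" in region or "central" in region:
            return GeoGroup.NEA
        return GeoGroup.UNASSIGNED

    if country == "south africa":
        return GeoGroup.SA
    if country in _NEA_COUNTRIES:
        return GeoGroup.NEA
    if country in _MED_COUNTRIES:
        return GeoGroup.MED
    if country in _AFR_COUNTRIES:
        return GeoGroup.AFR
    if country in _AUS_COUNTRIES:
        return GeoGroup.AUS
    if country in _ASI_COUNTRIES:
        return GeoGroup.ASI
    return GeoGroup.UNASSIGNED


def variable_sites(aln: Alignment) -> list[int]:
    """0-based indices of columns with ≥2 distinct unambiguous bases.

    Only A/C/G/T count as states; gaps and missing cells are ignored, so a
    column is variable only among the records that actually observe it.
    """
    mat = aln.matrix
    present = np.stack([(mat == b).any(axis=0) for b in range(4)])
    return np.flatnonzero(present.sum(axis=0) >= 2).tolist()
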