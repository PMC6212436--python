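"""Readers/writers for sequence and tabular inputs plus the canonical data model.

Sequences are stored uppercase over the alphabet {A,C,G,T,-,N}; IUPAC
ambiguity codes other than N are normalised to N so that pairwise identity is
always well defined. The occurrence table of the two surveyed recipient
regions (BB = Bay of Biscay, GL = Gulf of Lion) ships as a versioned CSV
fixture packaged with the code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MARKERS = ("COI", "16S", "18S")
_VALID = set("ACGT-N")
_AMBIG = set("RYSWKMBDHV")  # IUPAC ambiguity codes collapsed to N


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class AlignmentError(ValueError):
    """Raised when sequences meant to be aligned have unequal lengths."""


class ReferenceJoinError(KeyError):
    """Raised when FASTA ids and the metadata table do not join 1:1."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map ambiguity codes other than N to N."""
    out = []
    for ch in seq.upper():
        if ch in _VALID:
            out.append(ch)
        elif ch in _AMBIG:
            out.append("N")
        else:
            raise ValueError(f"unexpected character {ch!r} in sequence")
    return "".join(out)


@dataclass
class AlignedSequenceSet:
    """A per-species, per-recipient-region alignment of barcode sequences.

    Parameters
    ----------
    species : taxon name.
    region : recipient region label (e.g. "BB", "GL").
    sequences : list of (sample_id, aligned sequence) pairs, all equal length.
    marker : barcode marker, one of COI/16S/18S.
    """

    species: str = ""
    region: str = ""
    sequences: list[tuple[str, str]] = field(default_factory=list)
    marker: str = "COI"

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"marker must be one of {MARKERS}, got {self.marker!r}")
        self.sequences = [(sid, normalize_sequence(s)) for sid, s in self.sequences]
        if self.sequences:
            L = len(self.sequences[0][1])
            if L == 0:
                raise AlignmentError("zero-length alignment")
            for sid, s in self.sequences:
                if len(s) != L:
                    raise AlignmentError(
                        f"ragged alignment: {sid!r} has length {len(s)}, expected {L}"
                    )
            ids = [sid for sid, _ in self.sequences]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample ids in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class NISRecord:
    """One occurrence-table row: a NIS/cryptogenic population in one region.

    ``pct`` is the percentage over the regional barcoded total; ``natives`` is
    the mean native species richness at the sites where the NIS occurred;
    ``cargo_pct`` the percentage of import tons from the native range over
    total regional imports; ``distance`` the distance (thousand nautical
    miles) to the centre of the putative donor region. Cryptogenic rows carry
    neither cargo nor distance.
    """

    species: str
    region: str
    native_range: str
    vector: str
    n: int
    pct: float
    NH: int
    Hd: float
    pi: float
    natives: float | None = None
    cargo_pct: float | None = None
    distance: float | None = None
    lat_crosses: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.Hd <= 1.0):
            raise ValueError("Hd must lie in [0, 1]")
        if not (1 <= self.NH <= self.n):
            raise ValueError("NH must satisfy 1 <= NH <= n")
        if self.pi < 0:
            raise ValueError("pi must be >= 0")
        if self.is_cryptogenic and (self.distance is not None or self.cargo_pct is not None):
            raise ValueError("cryptogenic rows carry no distance/cargo")

    @property
    def is_cryptogenic(self) -> bool:
        return self.native_range == "Cryptogenic"


@dataclass
class ReferenceRecord:
    """A geo-referenced reference haplotype from a public database.

    Non-voucher records are kept but flagged; donor inference excludes them by
    default because only voucher-backed, geographically referenced sequences
    support a geographic assignment.
    """

    ref_id: str
    species: str
    sequence: str
    region: str
    centroid: tuple[float, float]
    voucher: bool = True

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.voucher and not self.region:
            raise ValueError("voucher reference must carry a region label")


def read_fasta(
    path: str | Path,
    species: str = "",
    region: str = "",
    marker: str = "COI",
) -> AlignedSequenceSet:
    """Read an aligned FASTA file into an :class:`AlignedSequenceSet`.

    Sequences are uppercased and ambiguity codes collapsed to N; ragged
    alignments raise :class:`AlignmentError`.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises variously
        raise FastaParseError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    seqs = [(rec.id, str(rec.seq)) for rec in records]
    return AlignedSequenceSet(species=species, region=region, sequences=seqs, marker=marker)


def write_fasta(seqs: AlignedSequenceSet, path: str | Path) -> None:
    """Write an alignment back to FASTA (round-trips ids and sequences)."""
    records = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def records_from_dataframe(df: pd.DataFrame) -> list[NISRecord]:
    """Build validated :class:`NISRecord` rows from an occurrence table."""
    required = {"species", "region", "native_range", "vector", "n", "pct",
                "NH", "Hd", "pi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(NISRecord(
            species=str(row["species"]),
            region=str(row["region"]),
            native_range=str(row["native_range"]),
            vector=str(row["vector"]),
            n=int(row["n"]),
            pct=float(row["pct"]),
            NH=int(row["NH"]),
            Hd=float(row["Hd"]),
            pi=float(row["pi"]),
            natives=_opt(row.get("natives")),
            cargo_pct=_opt(row.get("cargo_pct")),
            distance=_opt(row.get("distance")),
            lat_crosses=_opt(row.get("lat_crosses")),
        ))
    return out


def read_occurrence_table(path: str | Path) -> list[NISRecord]:
    """Read a user-supplied occurrence CSV with the fixture's column schema."""
    return records_from_dataframe(pd.read_csv(path))


def load_table1_fixture() -> list[NISRecord]:
    """Load the packaged occurrence table of the two surveyed regions.

    22 populations (18 Bay of Biscay + 4 Gulf of Lion); the ``n`` column sums
    to 253 (BB) and 44 (GL). The GL percentage denominator is the barcoded
    total (163 individuals).
    """
    with resources.files("nistrace.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return records_from_dataframe(df)


# Regional totals used for the percentage denominators: barcoded individuals
# per recipient region and the grand total.
BARCODED_TOTALS = {"BB": 671, "GL": 163}
GRAND_TOTAL = 834


def read_reference_db(fasta: str | Path, metadata: str | Path) -> list[ReferenceRecord]:
    """Join a reference FASTA with its metadata table into ReferenceRecords.

    The metadata file (CSV or TSV, sniffed from the extension) must contain
    columns ref_id, species, region, lat, lon, voucher and cover every FASTA
    id; an id without a metadata row raises :class:`ReferenceJoinError`
    naming the offending id.
    """
    sep = "\t" if str(metadata).endswith((".tsv", ".tab")) else ","
    meta = pd.read_csv(metadata, sep=sep)
    required = {"ref_id", "species", "region", "lat", "lon", "voucher"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"reference metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("ref_id")
    records = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in meta.index:
            raise ReferenceJoinError(f"reference {rec.id!r} has no metadata row")
        row = meta.loc[rec.id]
        records.append(ReferenceRecord(
            ref_id=rec.id,
            species=str(row["species"]),
            sequence=str(rec.seq),
            region=str(row["region"]) if not pd.isna(row["region"]) else "",
            centroid=(float(row["lat"]), float(row["lon"])),
            voucher=bool(row["voucher"]),
        ))
    return records
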