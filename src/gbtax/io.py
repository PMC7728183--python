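"""Sequence records, file I/O and run configuration.

The three sequence views of one organism are kept separate because the
relatedness indices consume different inputs: whole-genome nucleotide
sequence (ANI, dDDH), the predicted proteome (AAI, POCP), and the CDS
nucleotide set (gANI/AF).  FASTA reading/writing goes through Biopython;
files ending in ``.gz`` (or starting with the gzip magic) are handled
transparently.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("gbtax")

# Alphabets used for validation.  Protein includes the ambiguity/stop symbols
# that annotation pipelines occasionally emit.
DNA_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

#: float formatting used by every tabular writer
INDEX_DECIMALS = 4
SUPPORT_DECIMALS = 2


class FastaParseError(ValueError):
    """Raised when a FASTA record is malformed or violates its alphabet."""


@dataclass(frozen=True)
class SeqEntry:
    """One FASTA record: id (first whitespace-delimited token) and sequence."""

    id: str
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass(frozen=True)
class GenomeRecord:
    """Nucleotide view of one organism: one or more contigs."""

    genome_id: str
    contigs: tuple[SeqEntry, ...]

    @property
    def length(self) -> int:
        return sum(len(c.seq) for c in self.contigs)


@dataclass(frozen=True)
class Proteome:
    """Predicted protein sequences of one organism."""

    genome_id: str
    proteins: tuple[SeqEntry, ...]

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class GeneSet:
    """CDS nucleotide sequences of one organism (same ids as the proteome)."""

    genome_id: str
    genes: tuple[SeqEntry, ...]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def total_length(self) -> int:
        return sum(len(g.seq) for g in self.genes)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SeqEntry]:
    """Read FASTA records, preserving order; ids are cut at first whitespace.

    Parameters
    ----------
    path:
        Plain or gzip-compressed FASTA file.
    alphabet:
        ``"dna"``, ``"protein"`` or ``None`` (no validation).
    """
    path = Path(path)
    allowed = None
    if alphabet == "dna":
        allowed = DNA_ALPHABET
    elif alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    elif alphabet is not None:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    entries: list[SeqEntry] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            s = str(rec.seq).upper()
            if allowed is not None:
                bad = set(s) - allowed
                if bad:
                    raise FastaParseError(
                        f"{path}: record {rec.id!r} contains illegal "
                        f"character(s) {sorted(bad)} for alphabet {alphabet}"
                    )
            entries.append(SeqEntry(id=rec.id, seq=s))
    if not entries:
        logger.warning("empty FASTA file: %s", path)
    return entries


def write_fasta(entries: Iterable[SeqEntry], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(e.seq), id=e.id, description="") for e in entries
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def translate_cds(cds: str) -> str:
    """Translate a CDS (with terminal stop codon) to its protein sequence."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in CDS")
    return prot


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def format_value(x: float | None, decimals: int = INDEX_DECIMALS) -> str:
    if x is None:
        return "NA"
    return f"{x:.{decimals}f}"


def write_tsv(rows: Sequence[Mapping[str, object]], path: str | Path,
              columns: Sequence[str] | None = None) -> None:
    """Write a long-format TSV with a fixed column order (the canonical
    inter-stage format; square matrices are derived views)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            out = []
            for c in columns:
                v = row.get(c)
                if isinstance(v, float):
                    out.append(format_value(v))
                elif v is None:
                    out.append("NA")
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeInputs:
    """Paths to the sequence views of one genome; any view may be absent."""

    genome_id: str
    genome_fasta: str | None = None
    proteome_fasta: str | None = None
    cds_fasta: str | None = None
    rrna_fasta: str | None = None


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    The single ``seed`` drives every source of randomness (simulation,
    bootstrap); it is recorded in the output manifest.
    """

    genomes: list[GenomeInputs] = field(default_factory=list)
    indices: list[str] = field(default_factory=lambda: ["AAI"])
    out_dir: str = "gbtax_out"
    seed: int = 0
    clades_tsv: str | None = None
    marker_fasta: str | None = None
    bootstrap_replicates: int = 100
    log_level: str = "INFO"
    # free-form parameter overrides forwarded to the index functions
    params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        genomes = [GenomeInputs(**g) for g in raw.pop("genomes", [])]
        cfg = cls(genomes=genomes, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for g in self.genomes:
            for attr in ("genome_fasta", "proteome_fasta", "cds_fasta", "rrna_fasta"):
                p = getattr(g, attr)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{g.genome_id}: {attr} path {p!r} does not exist")
        if self.clades_tsv is not None and not Path(self.clades_tsv).exists():
            raise FileNotFoundError(f"clades_tsv path {self.clades_tsv!r} does not exist")

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "genomes": [vars(g) for g in self.genomes],
                "indices": self.indices,
                "seed": self.seed,
                "clades_tsv": self.clades_tsv,
                "marker_fasta": self.marker_fasta,
                "bootstrap_replicates": self.bootstrap_replicates,
                "params": self.params,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_clades_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (genome_id, clade) TSV, with or without a header."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected 2 tab-separated columns")
            if i == 0 and parts[0].lower() in {"genome_id", "genome", "id"}:
                continue
            out[parts[0]] = parts[1]
    return out
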