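"""Sequence ingestion and feature-matrix construction.

This module turns raw inputs — genome nucleotide FASTA, predicted-protein
FASTA and profile-HMM search results in HMMER3 per-target tabular ("tblout")
format — into the single model input used everywhere downstream: a matrix of
genomes × (GC content + binary GVOG presence/absence).

GVOGs (giant virus orthologous groups) are protein families modelled as
profile HMMs; a genome "has" a GVOG when at least one of its predicted
proteins hits that profile with a full-sequence E-value at or below the
significance threshold (default 1e-10).  Presence is binary, never a hit
count or bit score, so that genome completeness does not inflate features;
genome size is deliberately never a feature for the same reason.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
import shutil
import subprocess
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("gvtax")

DEFAULT_EVALUE_THRESHOLD = 1e-10

#: Prodigal-style protein ids are "<contig>_<n>"; the genome/contig id is the
#: prefix before the last underscore.
PRODIGAL_ID_PATTERN = re.compile(r"^(?P<genome>.+)_\d+$")

GROUPING_MODES = ("one-genome-per-file", "one-genome-per-record", "id-prefix")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """A genome (isolate or MAG) as an ordered set of contigs."""

    genome_id: str
    contigs: list[tuple[str, str]]  # (contig_id, nucleotide sequence)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"duplicate contig id(s) in genome {self.genome_id!r}: {dupes}"
            )
        for cid, seq in self.contigs:
            if len(seq) == 0:
                raise ValueError(
                    f"empty sequence for contig {cid!r} in genome {self.genome_id!r}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)


@dataclass
class ProteinSet:
    """Predicted proteins of one genome."""

    genome_id: str
    proteins: list[tuple[str, str]]  # (protein_id, amino-acid sequence)

    def protein_ids(self) -> list[str]:
        return [pid for pid, _ in self.proteins]


@dataclass(frozen=True)
class HmmHit:
    """One retained line of hmmsearch tblout: a protein × GVOG match."""

    protein_id: str
    gvog_id: str
    full_seq_evalue: float
    full_seq_score: float


@dataclass
class FeatureMatrix:
    """Genomes × features; column 0 is GC content, the rest binary GVOG presence.

    Column order is fixed at construction and persisted with any trained
    model; prediction-time inputs are aligned to a model's stored order by
    feature name.
    """

    genome_ids: list[str]
    feature_names: list[str]  # ["gc_content"] + GVOG ids
    values: np.ndarray  # shape (n_genomes, n_features), float

    def __post_init__(self) -> None:
        self.genome_ids = [str(g) for g in self.genome_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genome_ids), len(self.feature_names)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.feature_names)} features"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genome_ids, columns=self.feature_names
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise ValueError(f"unknown feature name(s): {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            genome_ids=list(self.genome_ids),
            feature_names=list(names),
            values=self.values[:, idx],
        )

    def write_tsv(self, path: str | Path, sidecar: Mapping | None = None) -> None:
        """Write the matrix as TSV plus a sidecar JSON with feature order."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="genome_id")
        meta = {"feature_names": self.feature_names}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1) + "\n"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        return cls(
            genome_ids=[str(g) for g in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# FASTA reading
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: Path) -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_genomes(
    fasta_path: str | Path,
    grouping_mode: str = "one-genome-per-file",
    genome_id: str | None = None,
    prefix_sep: str = "_",
) -> list[GenomeRecord]:
    """Read a nucleotide FASTA into one or more :class:`GenomeRecord`.

    grouping_mode controls how records map to genomes:

    - ``one-genome-per-file``: all records are contigs of a single genome
      named after the file stem (or ``genome_id``).
    - ``one-genome-per-record``: each record is a single-contig genome.
    - ``id-prefix``: records are grouped by the id prefix before the last
      ``prefix_sep`` in the record id.
    """
    if grouping_mode not in GROUPING_MODES:
        raise ValueError(
            f"grouping_mode must be one of {GROUPING_MODES}, got {grouping_mode!r}"
        )
    fasta_path = Path(fasta_path)
    with _open_maybe_gzip(fasta_path) as fh:
        try:
            records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
        except ValueError as exc:  # Biopython reports the offending content
            raise ValueError(f"malformed FASTA in {fasta_path}: {exc}") from exc
    if not records:
        logger.warning("no sequences found in %s", fasta_path)
        return []
    for rid, seq in records:
        if not seq:
            raise ValueError(f"empty sequence for record {rid!r} in {fasta_path}")

    if grouping_mode == "one-genome-per-file":
        gid = genome_id if genome_id is not None else fasta_path.name.split(".")[0]
        return [GenomeRecord(genome_id=gid, contigs=records)]
    if grouping_mode == "one-genome-per-record":
        return [GenomeRecord(genome_id=rid, contigs=[(rid, seq)]) for rid, seq in records]
    # id-prefix
    grouped: dict[str, list[tuple[str, str]]] = {}
    for rid, seq in records:
        prefix = rid.rsplit(prefix_sep, 1)[0] if prefix_sep in rid else rid
        grouped.setdefault(prefix, []).append((rid, seq))
    return [GenomeRecord(genome_id=g, contigs=c) for g, c in grouped.items()]


def write_genomes_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for genome in genomes:
            for cid, seq in genome.contigs:
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_proteins(
    fasta_path: str | Path,
    genome_id: str | None = None,
    id_pattern: re.Pattern | None = None,
    known_genomes: Sequence[str] | None = None,
) -> list[ProteinSet]:
    """Read a protein FASTA into per-genome :class:`ProteinSet` objects.

    With ``genome_id`` given, all proteins belong to that genome.  Otherwise
    protein ids are mapped to genomes by ``id_pattern`` (default: the
    Prodigal ``<contig>_<n>`` convention, stripping the trailing ``_<n>``).
    When ``known_genomes`` is supplied, a longest-prefix match against it
    takes precedence so contig-bearing ids resolve to their genome.
    """
    fasta_path = Path(fasta_path)
    with _open_maybe_gzip(fasta_path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if genome_id is not None:
        return [ProteinSet(genome_id=genome_id, proteins=records)]
    pattern = id_pattern or PRODIGAL_ID_PATTERN
    grouped: dict[str, list[tuple[str, str]]] = {}
    for pid, seq in records:
        gid = map_protein_to_genome(pid, pattern=pattern, known_genomes=known_genomes)
        grouped.setdefault(gid, []).append((pid, seq))
    return [ProteinSet(genome_id=g, proteins=p) for g, p in grouped.items()]


def map_protein_to_genome(
    protein_id: str,
    pattern: re.Pattern = PRODIGAL_ID_PATTERN,
    known_genomes: Sequence[str] | None = None,
) -> str:
    """Resolve a protein id to its genome id.

    Prodigal names proteins ``<contig>_<n>``; stripping the last ``_<n>``
    yields the contig, which for single-contig genomes is the genome id.
    ``known_genomes`` enables prefix resolution for multi-contig ids like
    ``genome_contig3_12``.
    """
    if known_genomes:
        candidates = [g for g in known_genomes if protein_id.startswith(g)]
        if candidates:
            return max(candidates, key=len)
    m = pattern.match(protein_id)
    if not m:
        raise ValueError(
            f"protein id {protein_id!r} does not match the configured id convention"
        )
    return m.group("genome")


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def compute_gc(genome: GenomeRecord) -> float:
    """GC fraction over all contigs: (G+C)/(A+C+G+T), case-insensitive.

    Ambiguity codes (including N) are excluded from both numerator and
    denominator.  Contigs are effectively concatenated, i.e. the result is
    length-weighted, not a mean of per-contig fractions.
    """
    gc = 0
    atcg = 0
    for _, seq in genome.contigs:
        s = seq.upper()
        g = s.count("G")
        c = s.count("C")
        gc += g + c
        atcg += g + c + s.count("A") + s.count("T")
    if atcg == 0:
        raise ValueError(
            f"genome {genome.genome_id!r} has no unambiguous bases (A/C/G/T)"
        )
    return gc / atcg


# ---------------------------------------------------------------------------
# HMMER tblout parsing
# ---------------------------------------------------------------------------

def parse_hmm_hits(
    tblout: str | Path | TextIO,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[HmmHit]:
    """Parse HMMER3 per-target tabular output, keeping significant hits.

    Accepts a path, tblout text, or an open text stream.  Columns follow the
    hmmsearch convention: target (protein), target accession, query (GVOG
    profile), query accession, full-sequence E-value, full-sequence score.
    Hits with full-sequence E-value <= ``evalue_threshold`` (inclusive) are
    retained.
    """
    if hasattr(tblout, "read"):
        stream: TextIO = tblout  # type: ignore[assignment]
        name = getattr(tblout, "name", "<stream>")
    else:
        text_or_path = str(tblout)
        if "\n" in text_or_path or not Path(text_or_path).exists():
            if "\n" not in text_or_path:
                raise FileNotFoundError(f"tblout file not found: {text_or_path}")
            stream = StringIO(text_or_path)
            name = "<text>"
        else:
            stream = open(text_or_path)
            name = text_or_path

    hits: list[HmmHit] = []
    for lineno, line in enumerate(stream, start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(
                f"{name}:{lineno}: expected >= 6 whitespace-delimited columns, "
                f"got {len(fields)}"
            )
        try:
            evalue = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise ValueError(
                f"{name}:{lineno}: non-numeric E-value/score field "
                f"({fields[4]!r}, {fields[5]!r})"
            ) from exc
        if evalue < 0:
            raise ValueError(f"{name}:{lineno}: negative E-value {evalue}")
        if evalue <= evalue_threshold:
            hits.append(
                HmmHit(
                    protein_id=fields[0],
                    gvog_id=fields[2],
                    full_seq_evalue=evalue,
                    full_seq_score=score,
                )
            )
    if stream is not tblout and not isinstance(stream, StringIO):
        stream.close()
    return hits


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def build_feature_matrix(
    genomes: Sequence[GenomeRecord],
    protein_sets: Sequence[ProteinSet],
    hits: Sequence[HmmHit],
    gvog_ids: Sequence[str],
) -> FeatureMatrix:
    """Assemble the genomes × (gc_content + GVOG presence) matrix.

    Cell (g, v) is 1 iff at least one retained hit of any protein of genome
    g matches GVOG v (presence, not count).  Hits to GVOGs outside
    ``gvog_ids`` are ignored.  A hit whose protein belongs to no known
    genome is an error.
    """
    gids = [g.genome_id for g in genomes]
    if len(gids) != len(set(gids)):
        raise ValueError("duplicate genome ids in collection")
    genome_index = {g: i for i, g in enumerate(gids)}
    protein_to_genome = {
        pid: ps.genome_id for ps in protein_sets for pid in ps.protein_ids()
    }
    gvog_index = {v: j for j, v in enumerate(gvog_ids)}

    values = np.zeros((len(genomes), 1 + len(gvog_ids)))
    for i, genome in enumerate(genomes):
        values[i, 0] = compute_gc(genome)

    orphans = []
    for hit in hits:
        gid = protein_to_genome.get(hit.protein_id)
        if gid is None or gid not in genome_index:
            orphans.append(hit.protein_id)
            continue
        j = gvog_index.get(hit.gvog_id)
        if j is not None:
            values[genome_index[gid], 1 + j] = 1.0
    if orphans:
        raise ValueError(
            "hits reference proteins of unknown genomes: "
            + ", ".join(sorted(set(orphans))[:20])
        )
    return FeatureMatrix(
        genome_ids=gids,
        feature_names=["gc_content"] + list(gvog_ids),
        values=values,
    )


# ---------------------------------------------------------------------------
# Optional external-tool wrappers (never required by the rest of the package)
# ---------------------------------------------------------------------------

def run_prodigal(
    genome_fasta: str | Path,
    out_protein_fasta: str | Path,
    binary: str = "prodigal",
    mode: str = "meta",
) -> None:
    """Shell out to Prodigal with default parameters to predict proteins."""
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"gene-caller binary {binary!r} not found on PATH; supply a "
            "pre-computed protein FASTA instead, or install Prodigal"
        )
    subprocess.run(
        [binary, "-i", str(genome_fasta), "-a", str(out_protein_fasta), "-p", mode],
        check=True,
        capture_output=True,
    )


def run_hmmsearch(
    protein_fasta: str | Path,
    hmm_db: str | Path,
    out_tblout: str | Path,
    binary: str = "hmmsearch",
    evalue: float = DEFAULT_EVALUE_THRESHOLD,
) -> None:
    """Shell out to hmmsearch, writing per-target tabular output."""
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"HMMER binary {binary!r} not found on PATH; supply a pre-computed "
            "tblout file instead, or install HMMER3"
        )
    subprocess.run(
        [
            binary,
            "--tblout",
            str(out_tblout),
            "-E",
            str(evalue),
            str(hmm_db),
            str(protein_fasta),
        ],
        check=True,
        capture_output=True,
    )
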