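"""One-way average amino acid identity (AAI) best-match search.

Beyond a taxonomic class label, it is often useful to know which reference
genome a query most resembles.  The query's predicted proteins are searched
one-way against a taxonomy-annotated reference protein database (one
representative proteome per genus); for each reference genome the best hit
per query protein is kept, and

- AAI   = mean percent identity of those best hits,
- AF    = alignment fraction: 100 x (query proteins with a qualifying hit)
          / (total query proteins).

To avoid spurious matches driven by a handful of shared proteins, a query ×
reference pair with AF below a floor (default 20) reports an AAI of 0 (the
raw mean is retained in a side field).  The best match is the reference
genome maximizing the reported AAI, ties broken by higher AF then by genome
id.

The default alignment backend is an in-process Smith-Waterman (Biopython's
``PairwiseAligner`` in local mode, BLOSUM62, affine gap penalties -11/-1),
so no external binary is ever required; external ``lastal`` or ``blastp``
backends can be selected for large databases.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_features import ProteinSet, read_proteins

DEFAULT_AF_FLOOR = 20.0
#: Builtin backend's reporting threshold: local-alignment raw score below
#: which a pair is not considered a hit.  Random same-length protein pairs
#: score well below this; genuinely homologous pairs well above.
DEFAULT_MIN_SCORE = 50.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinAlignmentHit:
    query_protein_id: str
    ref_protein_id: str
    ref_genome_id: str
    percent_identity: float  # in [0, 100]
    alignment_length: int
    score: float


@dataclass
class AAIResult:
    query_genome_id: str
    best_match_genome_id: str | None
    aai: float  # reported value; 0 when af < af_floor
    af: float
    match_taxonomy: tuple[str, str, str] | None  # (order, family, genus)
    raw_aai: float = 0.0  # mean best-hit identity before the AF floor rule


@dataclass
class BackendConfig:
    backend: str = "builtin"  # "builtin" | "last" | "blastp"
    min_score: float = DEFAULT_MIN_SCORE
    binary: str | None = None  # override the external binary name


@dataclass
class ReferenceDatabase:
    """Reference proteomes plus per-genome (order, family, genus) taxonomy."""

    proteins: list[ProteinSet]
    taxonomy: dict[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        for ps in self.proteins:
            if ps.genome_id not in self.taxonomy:
                raise ValueError(
                    f"reference genome {ps.genome_id!r} has no taxonomy entry"
                )

    @property
    def genome_ids(self) -> list[str]:
        return [ps.genome_id for ps in self.proteins]

    @classmethod
    def from_files(
        cls, protein_fasta: str | Path, taxonomy_tsv: str | Path
    ) -> "ReferenceDatabase":
        tax_df = pd.read_csv(taxonomy_tsv, sep="\t", dtype=str)
        required = {"genome_id", "order", "family", "genus"}
        if not required.issubset(tax_df.columns):
            raise ValueError(f"taxonomy table must have columns {sorted(required)}")
        taxonomy = {
            r.genome_id: (r.order, r.family, r.genus)
            for r in tax_df.itertuples(index=False)
        }
        protein_sets = read_proteins(
            protein_fasta, known_genomes=list(taxonomy)
        )
        return cls(proteins=protein_sets, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# Alignment backends
# ---------------------------------------------------------------------------

def _builtin_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner

def _percent_identity(alignment) -> tuple[float, int]:
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    if length == 0:
        return 0.0, 0
    return 100.0 * counts.identities / length, int(length)


def _search_builtin(
    query: ProteinSet, reference_db: ReferenceDatabase, config: BackendConfig
) -> list[ProteinAlignmentHit]:
    aligner = _builtin_aligner()
    hits: list[ProteinAlignmentHit] = []
    for qid, qseq in query.proteins:
        for ref in reference_db.proteins:
            best_score = -np.inf
            best_rid = None
            best_rseq = None
            for rid, rseq in ref.proteins:
                score = aligner.score(qseq, rseq)
                if score > best_score or (score == best_score and best_rid is not None and rid < best_rid):
                    best_score, best_rid, best_rseq = score, rid, rseq
            if best_rid is None or best_score < config.min_score:
                continue
            alignment = aligner.align(qseq, best_rseq)[0]
            pident, length = _percent_identity(alignment)
            hits.append(
                ProteinAlignmentHit(
                    query_protein_id=qid,
                    ref_protein_id=best_rid,
                    ref_genome_id=ref.genome_id,
                    percent_identity=pident,
                    alignment_length=length,
                    score=float(best_score),
                )
            )
    return hits


def _require_binary(name: str, hint: str) -> str:
    if shutil.which(name) is None:
        raise RuntimeError(
            f"alignment backend binary {name!r} not found on PATH. {hint}"
        )
    return name


def _search_blastp(
    query: ProteinSet, reference_db: ReferenceDatabase, config: BackendConfig
) -> list[ProteinAlignmentHit]:
    blastp = _require_binary(
        config.binary or "blastp",
        "Install NCBI BLAST+ or use the builtin backend (BackendConfig(backend='builtin')).",
    )
    makeblastdb = _require_binary("makeblastdb", "Install NCBI BLAST+.")
    protein_to_genome = {
        pid: ps.genome_id for ps in reference_db.proteins for pid in ps.protein_ids()
    }
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        ref_fa = tmp / "ref.faa"
        with open(ref_fa, "w") as fh:
            for ps in reference_db.proteins:
                for pid, seq in ps.proteins:
                    fh.write(f">{pid}\n{seq}\n")
        q_fa = tmp / "query.faa"
        with open(q_fa, "w") as fh:
            for pid, seq in query.proteins:
                fh.write(f">{pid}\n{seq}\n")
        subprocess.run(
            [makeblastdb, "-in", str(ref_fa), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        out = subprocess.run(
            [
                blastp,
                "-query",
                str(q_fa),
                "-db",
                str(ref_fa),
                "-outfmt",
                "6 qseqid sseqid pident length bitscore",
            ],
            check=True,
            capture_output=True,
            text=True,
        ).stdout
    best: dict[tuple[str, str], ProteinAlignmentHit] = {}
    for line in out.splitlines():
        qid, sid, pident, length, score = line.split("\t")
        gid = protein_to_genome[sid]
        hit = ProteinAlignmentHit(
            query_protein_id=qid,
            ref_protein_id=sid,
            ref_genome_id=gid,
            percent_identity=float(pident),
            alignment_length=int(length),
            score=float(score),
        )
        key = (qid, gid)
        if key not in best or hit.score > best[key].score:
            best[key] = hit
    return list(best.values())


def one_way_search(
    query: ProteinSet,
    reference_db: ReferenceDatabase,
    config: BackendConfig | None = None,
) -> list[ProteinAlignmentHit]:
    """Search query proteins against every reference proteome.

    Returns at most one hit per (query protein, reference genome): the
    highest-scoring alignment.  The builtin backend needs no external
    software; ``last``/``blastp`` shell out and raise a clear error when the
    binary is absent.
    """
    config = config or BackendConfig()
    if config.backend == "builtin":
        return _search_builtin(query, reference_db, config)
    if config.backend == "blastp":
        return _search_blastp(query, reference_db, config)
    if config.backend == "last":
        _require_binary(
            config.binary or "lastal",
            "Install LAST (https://gitlab.com/mcfrith/last) or use the builtin "
            "backend (BackendConfig(backend='builtin')).",
        )
        raise RuntimeError("LAST backend requires lastdb-formatted references")
    raise ValueError(f"unknown backend {config.backend!r}")


# ---------------------------------------------------------------------------
# AAI computation
# ---------------------------------------------------------------------------

def compute_aai(
    hits: Sequence[ProteinAlignmentHit],
    query: ProteinSet,
    ref_genome_id: str,
    af_floor: float = DEFAULT_AF_FLOOR,
    taxonomy: Mapping[str, tuple[str, str, str]] | None = None,
) -> AAIResult:
    """AAI and alignment fraction of one query against one reference genome.

    AF = 100 x (query proteins with >= 1 hit) / (total query proteins); AAI
    is the mean best-hit percent identity.  When AF < ``af_floor`` the
    reported AAI is 0; the unfloored mean stays in ``raw_aai``.
    """
    if not query.proteins:
        raise ValueError(f"query {query.genome_id!r} has no proteins")
    relevant = [h for h in hits if h.ref_genome_id == ref_genome_id]
    best_per_protein: dict[str, ProteinAlignmentHit] = {}
    for h in relevant:
        prev = best_per_protein.get(h.query_protein_id)
        if prev is None or h.score > prev.score:
            best_per_protein[h.query_protein_id] = h
    n_hit = len(best_per_protein)
    af = 100.0 * n_hit / len(query.proteins)
    raw = (
        float(np.mean([h.percent_identity for h in best_per_protein.values()]))
        if n_hit
        else 0.0
    )
    reported = raw if af >= af_floor else 0.0
    return AAIResult(
        query_genome_id=query.genome_id,
        best_match_genome_id=ref_genome_id,
        aai=reported,
        af=af,
        match_taxonomy=taxonomy.get(ref_genome_id) if taxonomy else None,
        raw_aai=raw,
    )


def best_match(
    query: ProteinSet,
    reference_db: ReferenceDatabase,
    config: BackendConfig | None = None,
    af_floor: float = DEFAULT_AF_FLOOR,
) -> AAIResult:
    """Best reference match of a query proteome by reported AAI.

    Ties are broken by higher AF, then lexicographically by genome id.  When
    no reference passes the AF floor the result has no match and AAI 0.
    """
    hits = one_way_search(query, reference_db, config)
    results = [
        compute_aai(hits, query, gid, af_floor, reference_db.taxonomy)
        for gid in reference_db.genome_ids
    ]
    passing = [r for r in results if r.af >= af_floor]
    if not passing:
        return AAIResult(
            query_genome_id=query.genome_id,
            best_match_genome_id=None,
            aai=0.0,
            af=0.0,
            match_taxonomy=None,
        )
    return min(passing, key=lambda r: (-r.aai, -r.af, r.best_match_genome_id))


def results_to_frame(results: Sequence[AAIResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        order, family, genus = r.match_taxonomy or ("", "", "")
        rows.append(
            {
                "query": r.query_genome_id,
                "best_match": r.best_match_genome_id or "",
                "AAI": r.aai,
                "AF": r.af,
                "order": order,
                "family": family,
                "genus": genus,
            }
        )
    return pd.DataFrame(rows)
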