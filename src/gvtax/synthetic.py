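"""Label-structured synthetic fixtures for end-to-end testing.

Real training data for giant-virus classifiers — curated genome databases and
thousands of profile HMMs — are far too large to ship with a test suite, so
this module generates datasets with the same *structure*: each taxonomic
class carries a characteristic set of GVOGs (order-level cores shared by the
order's families plus family-specific additions, the block pattern seen in
real presence/absence heatmaps), members of a class have each signature GVOG
with probability ``p_signature`` and any other GVOG with a small background
probability, and each class has its own GC-content offset.

Hits are materialized directly as HMMER3 tblout text (significant E-values
for present GVOGs, plus decoy lines above the threshold for absent ones), so
the parser and E-value filter are exercised without running any external
binary.  Each present GVOG is also assigned a gene coordinate on a contig;
fragmenting a genome retains only the GVOGs whose genes fall inside the
retained windows, so completeness genuinely degrades feature presence.

What this emulates, and what it does not: class-conditional GVOG presence,
collinearity of features within a lineage, multi-contig genomes, and
completeness-truncated variants.  It does not model real protein evolution,
assembly chimerism, or bin contamination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify_evaluate import TaxonLabelSet, order_bin
from .fragmentizer import AugmentationPolicy, fragment_plan
from .io_features import (
    FeatureMatrix,
    GenomeRecord,
    ProteinSet,
    build_feature_matrix,
    parse_hmm_hits,
    write_genomes_fasta,
)

DEFAULT_P_SIGNATURE = 0.9
DEFAULT_P_BACKGROUND = 0.02
GENE_LENGTH = 900  # nt footprint of one GVOG gene on its contig
PROTEIN_LENGTH = 80
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Order-level classes of the benchmark preset; Not_GV collects
#: non-giant-virus material (Mirusviricota, jumbo phage).
BENCHMARK_ORDERS = (
    "Algavirales",
    "Asfuvirales",
    "Chitovirales",
    "Imitervirales",
    "Pandoravirales",
    "Pimascovirales",
    "incertae_sedis",
    "Not_GV",
)
#: Families per order in the preset (13 family-level classes in total).
BENCHMARK_FAMILIES_PER_ORDER = (2, 1, 1, 3, 2, 2, 1, 1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSignature:
    """Presence model of one family-level class (nested in an order)."""

    class_name: str  # family-level class name
    order: str
    signature_gvogs: tuple[str, ...]
    p_signature: float
    p_background: float
    gc_mean: float
    gc_sd: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_background < self.p_signature <= 1):
            raise ValueError(
                "need 0 <= p_background < p_signature <= 1, got "
                f"({self.p_background}, {self.p_signature})"
            )


@dataclass
class ContigLengthModel:
    """How genomes are split into contigs."""

    genome_length_range: tuple[int, int] = (20_000, 40_000)
    n_contigs_range: tuple[int, int] = (1, 5)


@dataclass
class SyntheticDataset:
    """Genomes, proteomes, tblout text and labels generated from signatures."""

    genomes: list[GenomeRecord]
    protein_sets: list[ProteinSet]
    tblout: str
    labels: TaxonLabelSet
    gvog_ids: list[str]
    signatures: list[ClassSignature]
    seed: int
    presence: pd.DataFrame  # genomes x gvog pool, the drawn Bernoulli matrix
    gene_coords: dict[str, dict[str, tuple[str, int, int]]]
    completeness: dict[str, float] = field(default_factory=dict)

    def feature_matrix(self, evalue_threshold: float = 1e-10) -> FeatureMatrix:
        """Featurize exactly as the pipeline would: parse tblout, build matrix."""
        hits = parse_hmm_hits(StringIO(self.tblout), evalue_threshold)
        return build_feature_matrix(self.genomes, self.protein_sets, hits, self.gvog_ids)

    def write(self, outdir: str | Path) -> None:
        """Write FASTA / protein FASTA / tblout / labels TSV / manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genomes_fasta(self.genomes, outdir / "genomes.fna")
        with open(outdir / "proteins.faa", "w") as fh:
            for ps in self.protein_sets:
                for pid, seq in ps.proteins:
                    fh.write(f">{pid}\n{seq}\n")
        (outdir / "hits.tblout").write_text(self.tblout)
        self.labels.write_tsv(outdir / "labels.tsv")
        (outdir / "gvogs.txt").write_text("\n".join(self.gvog_ids) + "\n")
        manifest = {
            "seed": self.seed,
            "n_genomes": len(self.genomes),
            "n_gvogs": len(self.gvog_ids),
            "classes": sorted({s.class_name for s in self.signatures}),
            "orders": sorted({s.order for s in self.signatures}),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Signature construction
# ---------------------------------------------------------------------------

def make_signatures(
    n_orders: int,
    families_per_order: int | Sequence[int],
    gvogs_total: int,
    order_core_size: int = 12,
    family_size: int = 10,
    p_signature: float = DEFAULT_P_SIGNATURE,
    p_background: float = DEFAULT_P_BACKGROUND,
    seed: int = 0,
    order_names: Sequence[str] | None = None,
    gc_range: tuple[float, float] = (0.30, 0.60),
    gc_sd: float = 0.02,
) -> list[ClassSignature]:
    """Build hierarchical class signatures over a GVOG pool.

    Each order owns a core of ``order_core_size`` GVOGs shared by all its
    families; each family adds ``family_size`` GVOGs of its own.  All blocks
    are disjoint across orders and across families, so with
    ``order_core_size=0`` family signatures are pairwise disjoint.
    """
    if isinstance(families_per_order, int):
        families_per_order = [families_per_order] * n_orders
    families_per_order = list(families_per_order)
    if len(families_per_order) != n_orders:
        raise ValueError("families_per_order length must equal n_orders")
    demand = n_orders * order_core_size + sum(families_per_order) * family_size
    if demand > gvogs_total:
        raise ValueError(
            f"GVOG pool of {gvogs_total} cannot supply {demand} signature slots"
        )
    if order_names is None:
        order_names = [f"Order_{i + 1:02d}" for i in range(n_orders)]

    rng = np.random.default_rng(seed)
    pool = [f"GVOGm{i:04d}" for i in range(gvogs_total)]
    available = list(rng.permutation(pool))
    gc_means = np.linspace(gc_range[0], gc_range[1], n_orders)

    # family-class prefixes must be unique per order; fall back to the full
    # order name when two orders abbreviate to the same bin
    prefixes: dict[str, str] = {}
    for order in order_names:
        bin_ = order_bin(order)
        prefixes[order] = order if bin_ in prefixes.values() else bin_

    signatures: list[ClassSignature] = []
    pos = 0
    for oi, (order, n_fam) in enumerate(zip(order_names, families_per_order)):
        core = tuple(available[pos : pos + order_core_size])
        pos += order_core_size
        for fi in range(n_fam):
            fam_block = tuple(available[pos : pos + family_size])
            pos += family_size
            name = f"{prefixes[order]}_{fi + 1:02d}"
            signatures.append(
                ClassSignature(
                    class_name=name,
                    order=order,
                    signature_gvogs=core + fam_block,
                    p_signature=p_signature,
                    p_background=p_background,
                    gc_mean=float(gc_means[oi]),
                    gc_sd=gc_sd,
                )
            )
    return signatures


# ---------------------------------------------------------------------------
# Sequence materialization
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _random_protein(rng: np.random.Generator, length: int = PROTEIN_LENGTH) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _tblout_line(pid: str, gvog: str, evalue: float, score: float) -> str:
    return (
        f"{pid:<28} -          {gvog:<14} -            "
        f"{evalue:9.2e} {score:7.1f}   0.0  {evalue:9.2e} {score:7.1f}   0.0 "
        f"  1.0   1   0   0   1   1   1   1 -"
    )


def _materialize_genome(
    genome_id: str,
    present_gvogs: Sequence[str],
    gc: float,
    contig_model: ContigLengthModel,
    rng: np.random.Generator,
) -> tuple[GenomeRecord, ProteinSet, list[str], dict[str, tuple[str, int, int]]]:
    """One genome: contigs at the class GC, one protein + tblout line per
    present GVOG, and the gene coordinate of each present GVOG."""
    lo, hi = contig_model.genome_length_range
    total = int(rng.integers(lo, hi + 1))
    n_contigs = int(rng.integers(contig_model.n_contigs_range[0], contig_model.n_contigs_range[1] + 1))
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_contigs - 1, replace=False)) if n_contigs > 1 else np.array([], dtype=int)
    lengths = np.diff(np.concatenate([[0], cuts, [total]])).astype(int)
    # contig ids follow the <genome>_<n> convention so id-prefix grouping
    # reassembles genomes from a flat FASTA
    contigs = [
        (f"{genome_id}_{ci + 1}", _random_dna(int(L), gc, rng))
        for ci, L in enumerate(lengths)
    ]
    genome = GenomeRecord(genome_id=genome_id, contigs=contigs)

    proteins: list[tuple[str, str]] = []
    tblout_lines: list[str] = []
    coords: dict[str, tuple[str, int, int]] = {}
    weights = lengths / lengths.sum()
    for k, gvog in enumerate(present_gvogs, start=1):
        ci = int(rng.choice(len(contigs), p=weights))
        cid, cseq = contigs[ci]
        glen = min(GENE_LENGTH, len(cseq))
        start = int(rng.integers(0, len(cseq) - glen + 1))
        coords[gvog] = (cid, start, start + glen)
        pid = f"{genome_id}_{k}"
        proteins.append((pid, _random_protein(rng)))
        evalue = 10.0 ** float(rng.uniform(-40, -12))
        score = float(rng.uniform(60, 400))
        tblout_lines.append(_tblout_line(pid, gvog, evalue, score))
    return genome, ProteinSet(genome_id=genome_id, proteins=proteins), tblout_lines, coords


def sample_dataset(
    signatures: Sequence[ClassSignature],
    genomes_per_class: int,
    contig_length_model: ContigLengthModel | None = None,
    seed: int = 0,
    gvog_ids: Sequence[str] | None = None,
    decoy_rate: float = 0.05,
) -> SyntheticDataset:
    """Draw a labelled dataset from class signatures.

    Per genome: Bernoulli presence draws for every GVOG in the pool
    (``p_signature`` for the class's signature GVOGs, ``p_background``
    otherwise); present GVOGs become significant tblout lines, and a
    ``decoy_rate`` fraction of absent GVOGs is emitted with E-values above
    the 1e-10 threshold so the parser's filter is genuinely exercised.
    """
    if genomes_per_class < 1:
        raise ValueError("genomes_per_class must be >= 1")
    contig_model = contig_length_model or ContigLengthModel()
    if gvog_ids is None:
        union = sorted({g for s in signatures for g in s.signature_gvogs})
        n_pool = max(len(union) + 50, int(1.2 * len(union)))
        gvog_ids = sorted(set(union) | {f"GVOGm{i:04d}" for i in range(n_pool)})
    gvog_ids = list(gvog_ids)
    gvog_index = {g: i for i, g in enumerate(gvog_ids)}

    rng = np.random.default_rng(seed)
    genomes, protein_sets, all_lines = [], [], []
    labels: dict[str, tuple[str, str]] = {}
    gene_coords: dict[str, dict[str, tuple[str, int, int]]] = {}
    presence_rows = []
    row_ids = []
    counter = 0
    for sig in signatures:
        sig_mask = np.zeros(len(gvog_ids), dtype=bool)
        sig_mask[[gvog_index[g] for g in sig.signature_gvogs]] = True
        for _ in range(genomes_per_class):
            counter += 1
            gid = f"GEN{counter:05d}"
            p = np.where(sig_mask, sig.p_signature, sig.p_background)
            present = rng.random(len(gvog_ids)) < p
            present_gvogs = [g for g, m in zip(gvog_ids, present) if m]
            gc = float(np.clip(rng.normal(sig.gc_mean, sig.gc_sd), 0.2, 0.8))
            genome, proteins, lines, coords = _materialize_genome(
                gid, present_gvogs, gc, contig_model, rng
            )
            # decoy hits: absent GVOGs reported above the significance threshold
            absent = [g for g, m in zip(gvog_ids, present) if not m]
            n_decoys = rng.binomial(len(absent), decoy_rate)
            if n_decoys and proteins.proteins:
                for g in rng.choice(absent, size=n_decoys, replace=False):
                    pid = proteins.proteins[int(rng.integers(len(proteins.proteins)))][0]
                    evalue = 10.0 ** float(rng.uniform(-9, 1))
                    lines.append(_tblout_line(pid, g, evalue, float(rng.uniform(5, 20))))
            genomes.append(genome)
            protein_sets.append(proteins)
            all_lines.extend(lines)
            gene_coords[gid] = coords
            labels[gid] = (sig.order, sig.class_name)
            presence_rows.append(present.astype(int))
            row_ids.append(gid)

    header = (
        "#                                                               --- full sequence ---- "
        "--- best 1 domain ---- --- domain number estimation ----\n"
        "# target name        accession  query name           accession    E-value  score  bias "
        "  E-value  score  bias   exp reg clu  ov env dom rep inc description of target\n"
        "#------------------- ---------- -------------------- ---------- --------- ------ ----- "
        "--------- ------ -----   --- --- --- --- --- --- --- --- ---------------------\n"
    )
    return SyntheticDataset(
        genomes=genomes,
        protein_sets=protein_sets,
        tblout=header + "\n".join(all_lines) + "\n",
        labels=TaxonLabelSet(labels=labels),
        gvog_ids=gvog_ids,
        signatures=list(signatures),
        seed=seed,
        presence=pd.DataFrame(presence_rows, index=row_ids, columns=gvog_ids),
        gene_coords=gene_coords,
        completeness={gid: 1.0 for gid in row_ids},
    )


# ---------------------------------------------------------------------------
# Fragmentation with hit tracking
# ---------------------------------------------------------------------------

def fragment_with_hits(
    dataset: SyntheticDataset,
    genome_id: str,
    completeness: float,
    seed: int,
    fragment_id: str | None = None,
) -> tuple[GenomeRecord, ProteinSet, list[str]]:
    """Fragment one synthetic genome, keeping only hits whose gene coordinates
    fall entirely inside the retained windows."""
    source = next(g for g in dataset.genomes if g.genome_id == genome_id)
    rng = np.random.default_rng(seed)
    plan = fragment_plan(source, completeness, rng)
    fid = fragment_id if fragment_id is not None else f"{genome_id}.frag"
    seqs = dict(source.contigs)
    contigs = []
    for cid, start, end in plan:
        full = start == 0 and end == len(seqs[cid])
        new_id = cid if full else f"{cid}:{start + 1}-{end}"
        contigs.append((f"{fid}|{new_id}", seqs[cid][start:end]))
    fragment = GenomeRecord(genome_id=fid, contigs=contigs)

    windows: dict[str, list[tuple[int, int]]] = {}
    for cid, start, end in plan:
        windows.setdefault(cid, []).append((start, end))
    retained = [
        gvog
        for gvog, (cid, gstart, gend) in dataset.gene_coords[genome_id].items()
        if any(ws <= gstart and gend <= we for ws, we in windows.get(cid, []))
    ]
    proteins = []
    lines = []
    for k, gvog in enumerate(sorted(retained), start=1):
        pid = f"{fid}_{k}"
        proteins.append((pid, _random_protein(rng)))
        evalue = 10.0 ** float(rng.uniform(-40, -12))
        lines.append(_tblout_line(pid, gvog, evalue, float(rng.uniform(60, 400))))
    return fragment, ProteinSet(genome_id=fid, proteins=proteins), lines


def fragment_dataset(
    dataset: SyntheticDataset,
    policy: AugmentationPolicy,
    seed: int,
) -> SyntheticDataset:
    """Apply an augmentation policy to a synthetic dataset, hit-aware.

    Mirrors the plain-genome augmentation but regenerates each fragment's
    protein set and tblout lines from the genes that survive fragmentation,
    so downstream featurization sees genuinely degraded presence signatures.
    """
    genomes = list(dataset.genomes) if policy.include_originals else []
    protein_sets = list(dataset.protein_sets) if policy.include_originals else []
    tblout_parts = [dataset.tblout] if policy.include_originals else []
    labels = dict(dataset.labels.labels) if policy.include_originals else {}
    gene_coords = dict(dataset.gene_coords)
    completeness = dict(dataset.completeness) if policy.include_originals else {}

    master = np.random.SeedSequence(seed)
    for g, child in zip(dataset.genomes, master.spawn(len(dataset.genomes))):
        rng = np.random.default_rng(child)
        label = dataset.labels.labels[g.genome_id]
        k = 0
        for rule in policy.rules_for(g.genome_id, label):
            for _ in range(rule.fragments_per_genome):
                k += 1
                c = float(rng.uniform(rule.completeness_low, rule.completeness_high))
                frag_seed = int(rng.integers(0, 2**31 - 1))
                fid = f"{g.genome_id}.f{k}"
                frag, prots, lines = fragment_with_hits(
                    dataset, g.genome_id, c, frag_seed, fragment_id=fid
                )
                genomes.append(frag)
                protein_sets.append(prots)
                tblout_parts.append("\n".join(lines) + "\n" if lines else "")
                labels[fid] = label
                completeness[fid] = frag.total_length / g.total_length
    return SyntheticDataset(
        genomes=genomes,
        protein_sets=protein_sets,
        tblout="".join(tblout_parts),
        labels=TaxonLabelSet(labels=labels),
        gvog_ids=list(dataset.gvog_ids),
        signatures=list(dataset.signatures),
        seed=seed,
        presence=dataset.presence,
        gene_coords=gene_coords,
        completeness=completeness,
    )


# ---------------------------------------------------------------------------
# Paper-like preset
# ---------------------------------------------------------------------------

def benchmark_signatures(
    seed: int = 0,
    p_signature: float = DEFAULT_P_SIGNATURE,
    p_background: float = DEFAULT_P_BACKGROUND,
    gvogs_total: int = 400,
) -> list[ClassSignature]:
    """8 order-level classes (incl. Not_GV) with 13 family-level classes."""
    return make_signatures(
        n_orders=len(BENCHMARK_ORDERS),
        families_per_order=BENCHMARK_FAMILIES_PER_ORDER,
        gvogs_total=gvogs_total,
        p_signature=p_signature,
        p_background=p_background,
        seed=seed,
        order_names=BENCHMARK_ORDERS,
    )


def benchmark_dataset(
    seed: int = 0,
    genomes_per_class: int = 100,
    **signature_kwargs,
) -> SyntheticDataset:
    """The preset used for end-to-end recovery checks: well-separated
    hierarchical signatures, 100 genomes per family-level class."""
    signatures = benchmark_signatures(seed=seed, **signature_kwargs)
    return sample_dataset(signatures, genomes_per_class, seed=seed)
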