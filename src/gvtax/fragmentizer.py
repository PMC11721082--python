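"""Simulation of incomplete metagenome-assembled genomes (MAGs).

Genomes recovered from metagenomes by assembly and binning are routinely
incomplete: whole contigs are lost to the binning step and contig ends are
truncated.  To make classifiers robust to this, labelled training genomes are
augmented with fragmented variants at random completeness levels (completeness
= fragment length / source length).

Fragmentation mechanics: for a single-contig genome, one uniformly placed
contiguous window of the target length is taken; for a multi-contig genome,
contigs are shuffled (seeded), whole contigs are accumulated until the next
would exceed the target, and the final contig is trimmed (uniform window) to
land on the target length.  This mimics binning losing whole contigs while
preserving local contiguity.  Every fragment contig is therefore an exact
substring of a source contig, and fragments inherit the source's labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_features import GenomeRecord

#: Completeness bounds printed for the training-set augmentation.
TRAIN_COMPLETENESS_BOUNDS = (0.23, 0.99)
#: Completeness bounds printed for non-giant-virus training sequences and the test set.
NOT_GV_COMPLETENESS_BOUNDS = (0.29, 0.99)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSpec:
    """Provenance of one fragment: where it came from and at what completeness."""

    source_genome_id: str
    completeness: float
    seed: int
    fragment_id: str

    def __post_init__(self) -> None:
        if not (0 < self.completeness <= 1):
            raise ValueError(f"completeness must be in (0, 1], got {self.completeness}")


@dataclass(frozen=True)
class PolicyRule:
    """One augmentation rule: which genomes it covers and how many fragments
    at what completeness range they receive.

    ``selector`` is a predicate on (genome_id, label); rules are additive, so
    a genome matched by several rules receives the sum of their fragment
    counts (this is how a rare group can receive extra fragments on top of
    its lineage default).
    """

    name: str
    selector: Callable[[str, Any], bool]
    fragments_per_genome: int
    completeness_low: float
    completeness_high: float

    def __post_init__(self) -> None:
        if self.fragments_per_genome < 0:
            raise ValueError("fragments_per_genome must be >= 0")
        if not (0 < self.completeness_low <= self.completeness_high <= 1):
            raise ValueError(
                "completeness bounds must satisfy 0 < low <= high <= 1, got "
                f"({self.completeness_low}, {self.completeness_high})"
            )


@dataclass
class AugmentationPolicy:
    """A set of :class:`PolicyRule` plus whether originals are kept."""

    rules: list[PolicyRule]
    include_originals: bool = True

    def rules_for(self, genome_id: str, label: Any) -> list[PolicyRule]:
        return [r for r in self.rules if r.selector(genome_id, label)]

    def expected_total(self, labelled_ids: Mapping[str, Any]) -> int:
        """Output sequence count for a labelled set, without generating anything."""
        total = len(labelled_ids) if self.include_originals else 0
        for gid, label in labelled_ids.items():
            total += sum(r.fragments_per_genome for r in self.rules_for(gid, label))
        return total


def _order_of(label: Any) -> str:
    if hasattr(label, "order"):
        return label.order
    if isinstance(label, (tuple, list)):
        return label[0]
    return str(label)


def training_augmentation_policy(
    giant_fragments: int = 2,
    other_fragments: int = 1,
    rare_extra_fragments: int = 6,
    rare_orders: Sequence[str] = ("incertae_sedis",),
    not_gv_order: str = "Not_GV",
) -> AugmentationPolicy:
    """The stock training-set augmentation policy.

    Giant-virus genomes receive 2 fragments drawn at 23-99% completeness;
    non-giant-virus genomes (Mirusviricota, jumbo phage — the Not_GV group)
    receive 1 fragment at 29-99%; the rare Pokkesviricetes incertae sedis
    genomes receive 6 additional fragments on top of the giant-virus default.
    """
    lo, hi = TRAIN_COMPLETENESS_BOUNDS
    nlo, nhi = NOT_GV_COMPLETENESS_BOUNDS
    return AugmentationPolicy(
        rules=[
            PolicyRule(
                "giant_virus",
                lambda gid, lab: _order_of(lab) != not_gv_order,
                giant_fragments,
                lo,
                hi,
            ),
            PolicyRule(
                "not_gv",
                lambda gid, lab: _order_of(lab) == not_gv_order,
                other_fragments,
                nlo,
                nhi,
            ),
            PolicyRule(
                "rare_extra",
                lambda gid, lab: _order_of(lab) in rare_orders,
                rare_extra_fragments,
                lo,
                hi,
            ),
        ],
        include_originals=True,
    )


# ---------------------------------------------------------------------------
# Fragmentation mechanics
# ---------------------------------------------------------------------------

def fragment_plan(
    genome: GenomeRecord, completeness: float, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Choose the retained (contig_id, start, end) half-open windows for one fragment.

    Exposed separately so callers that track genomic coordinates (e.g. the
    synthetic-data generator tying gene positions to retained windows) can
    reuse the exact sampling mechanics.
    """
    if not (0 < completeness <= 1):
        raise ValueError(f"completeness must be in (0, 1], got {completeness}")
    total = genome.total_length
    target = int(round(completeness * total))
    target = max(1, min(target, total))
    if target == total:
        return [(cid, 0, len(seq)) for cid, seq in genome.contigs]

    if len(genome.contigs) == 1:
        cid, seq = genome.contigs[0]
        start = int(rng.integers(0, len(seq) - target + 1))
        return [(cid, start, start + target)]

    order = rng.permutation(len(genome.contigs))
    plan: list[tuple[str, int, int]] = []
    acc = 0
    for idx in order:
        cid, seq = genome.contigs[idx]
        remaining = target - acc
        if remaining <= 0:
            break
        if len(seq) <= remaining:
            plan.append((cid, 0, len(seq)))
            acc += len(seq)
        else:
            start = int(rng.integers(0, len(seq) - remaining + 1))
            plan.append((cid, start, start + remaining))
            acc += remaining
            break
    return plan


def fragmentize(
    genome: GenomeRecord,
    completeness: float,
    seed: int,
    fragment_id: str | None = None,
) -> GenomeRecord:
    """Produce one fragmented variant of ``genome`` at the given completeness.

    Deterministic under a fixed seed; the fragment's total length is
    round(completeness x source length) and every fragment contig is an exact
    substring of a source contig at its original coordinates.
    """
    rng = np.random.default_rng(seed)
    plan = fragment_plan(genome, completeness, rng)
    fid = fragment_id if fragment_id is not None else f"{genome.genome_id}.frag"
    contigs = []
    seqs = dict(genome.contigs)
    for cid, start, end in plan:
        full = start == 0 and end == len(seqs[cid])
        new_id = cid if full else f"{cid}:{start + 1}-{end}"
        contigs.append((f"{fid}|{new_id}", seqs[cid][start:end]))
    return GenomeRecord(genome_id=fid, contigs=contigs)


# ---------------------------------------------------------------------------
# Set-level augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentedSet:
    """Originals plus fragments, with inherited labels and a provenance manifest."""

    genomes: list[GenomeRecord]
    labels: dict[str, Any]
    manifest: pd.DataFrame  # fragment_id, source_id, target/achieved completeness, seed

    def write_manifest(self, path: str | Path) -> None:
        self.manifest.to_csv(path, sep="\t", index=False)


def augment_set(
    genomes: Sequence[GenomeRecord],
    labels: Mapping[str, Any],
    policy: AugmentationPolicy,
    seed: int,
) -> AugmentedSet:
    """Apply an :class:`AugmentationPolicy` to a labelled genome set.

    Fragment completeness is drawn uniformly from each rule's bounds;
    fragments inherit the source genome's label.  Output order and content
    are deterministic given (genomes, policy, seed).
    """
    unlabeled = [g.genome_id for g in genomes if g.genome_id not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled genome(s): {unlabeled[:10]}")

    out_genomes: list[GenomeRecord] = []
    out_labels: dict[str, Any] = {}
    rows = []
    if policy.include_originals:
        for g in genomes:
            out_genomes.append(g)
            out_labels[g.genome_id] = labels[g.genome_id]

    master = np.random.SeedSequence(seed)
    for g, child_seq in zip(genomes, master.spawn(len(genomes))):
        rng = np.random.default_rng(child_seq)
        k = 0
        for rule in policy.rules_for(g.genome_id, labels[g.genome_id]):
            for _ in range(rule.fragments_per_genome):
                k += 1
                completeness = float(
                    rng.uniform(rule.completeness_low, rule.completeness_high)
                )
                frag_seed = int(rng.integers(0, 2**31 - 1))
                fid = f"{g.genome_id}.f{k}"
                frag = fragmentize(g, completeness, frag_seed, fragment_id=fid)
                out_genomes.append(frag)
                out_labels[fid] = labels[g.genome_id]
                rows.append(
                    {
                        "fragment_id": fid,
                        "source_id": g.genome_id,
                        "rule": rule.name,
                        "target_completeness": completeness,
                        "achieved_completeness": frag.total_length / g.total_length,
                        "seed": frag_seed,
                    }
                )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "fragment_id",
            "source_id",
            "rule",
            "target_completeness",
            "achieved_completeness",
            "seed",
        ],
    )
    return AugmentedSet(genomes=out_genomes, labels=out_labels, manifest=manifest)
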