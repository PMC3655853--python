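"""Readers and writers for the package's plain-text formats.

FASTA goes through Biopython, Newick through the dendropy-backed
:class:`~sagkit.trees.AnnotatedTree`, tables through pandas.  All readers
validate on the way in (sequence alphabet, unique ids, state values) and
raise errors that name the offending record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binning import BinAssignment, ContigSet, WindowProfile
from .trees import AnnotatedTree

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_truth_labels",
    "write_truth_labels",
    "write_window_profiles",
    "write_assignments",
    "write_embedding",
    "read_ancestral_states",
    "write_ancestral_states",
    "read_identity_edges",
    "census_from_gene_table",
]

_ALLOWED = set("ACGTN")


def read_fasta(path) -> ContigSet:
    """Read contigs; ids are headers up to the first whitespace, sequences
    are uppercased and must contain only A, C, G, T or N."""
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"record {record.id!r} has an empty sequence")
        bad = next((i for i, ch in enumerate(seq) if ch not in _ALLOWED), None)
        if bad is not None:
            raise ValueError(
                f"record {record.id!r} has illegal character {seq[bad]!r} at offset {bad}"
            )
        entries.append((record.id, seq))
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return ContigSet(entries)  # ContigSet re-validates id uniqueness


def write_fasta(contigs: ContigSet, path) -> None:
    """Write 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path) -> AnnotatedTree:
    return AnnotatedTree.from_newick(Path(path).read_text())


def write_newick(tree: AnnotatedTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_truth_labels(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_truth_labels(truth: dict[str, str], path) -> None:
    pd.DataFrame(
        {"contig_id": list(truth), "source_label": list(truth.values())}
    ).to_csv(path, sep="\t", index=False)


def write_window_profiles(profiles: list[WindowProfile], path) -> None:
    rows = []
    for p in profiles:
        row = {"contig_id": p.contig_id, "start": p.start, "end": p.end, "gc": p.gc}
        row.update({f"f{i:03d}": v for i, v in enumerate(p.tetramer_freq)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_assignments(assignments: list[BinAssignment], path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": a.contig_id,
                "bin": a.bin_label if a.bin_label is not None else "NA",
                "confidence": a.confidence,
                "n_windows": a.n_windows,
                "flags": ",".join(a.flags),
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def write_embedding(coords: np.ndarray, path) -> None:
    frame = pd.DataFrame(
        coords, columns=[f"pc{i + 1}" for i in range(coords.shape[1])]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ancestral_states(path, tree: AnnotatedTree) -> AnnotatedTree:
    """Attach per-node presence states from a (node_id, family_id, state) TSV."""
    frame = pd.read_csv(path, sep="\t", dtype={"state": int})
    required = {"node_id", "family_id", "state"}
    if not required.issubset(frame.columns):
        raise ValueError(f"states table must have columns {sorted(required)}")
    bad = frame[~frame["state"].isin([0, 1])]
    if not bad.empty:
        raise ValueError(f"states must be 0/1; offending row: {bad.iloc[0].to_dict()}")
    universe = frozenset(frame["family_id"])
    states: dict[str, set] = {node: set() for node in frame["node_id"].unique()}
    for _, row in frame[frame["state"] == 1].iterrows():
        states[row["node_id"]].add(row["family_id"])
    return tree.with_states(states, family_universe=universe)


def write_ancestral_states(tree: AnnotatedTree, path) -> None:
    if tree.states is None:
        raise ValueError("tree carries no states to write")
    universe = sorted(tree.family_universe or frozenset())
    rows = [
        {"node_id": node, "family_id": fam, "state": int(fam in present)}
        for node, present in sorted(tree.states.items())
        for fam in universe
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_identity_edges(path) -> list[tuple[str, str, float]]:
    frame = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "identity"])
    return [
        (str(r.a), str(r.b), float(r.identity)) for r in frame.itertuples(index=False)
    ]


def census_from_gene_table(gene_table_path, universal_families) -> tuple[int, int, int]:
    """Compute (N, F, f) from a gene->family TSV and a universal-family list.

    The table has one row per predicted gene with columns ``gene`` and
    ``family`` (empty/NaN family means unassigned); N is the number of
    genes, f the number of universal families with at least one member.
    """
    frame = pd.read_csv(gene_table_path, sep="\t", dtype=str)
    if not {"gene", "family"}.issubset(frame.columns):
        raise ValueError("gene table must have columns 'gene' and 'family'")
    universal = set(universal_families)
    detected = set(frame["family"].dropna()) & universal
    return len(frame), len(universal), len(detected)
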