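"""Readers and writers for on-disk run artifacts.

Trace logs use the tab-separated dialect of BEAST-style loggers
(comment lines prefixed ``#``, a header row starting with ``Sample``),
so existing trace explorers can open them directly.  Tree logs are NEXUS
with a translate block; alignments are FASTA; checkpoints are versioned
JSON handled by the engine.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import Alignment, Tree

__all__ = [
    "TraceWriter",
    "read_trace_log",
    "NexusTreeWriter",
    "read_tree_log",
    "write_fasta",
    "read_fasta",
    "write_manifest",
    "read_manifest",
]


class TraceWriter:
    """Appends tab-separated sample rows under a ``Sample ...`` header."""

    def __init__(self, path, columns: Sequence[str], comments: Sequence[str] = (),
                 append: bool = False):
        self.path = Path(path)
        self.columns = list(columns)
        if self.columns[0] != "Sample":
            raise ValueError("first trace column must be 'Sample'")
        mode = "a" if append else "w"
        self._fh = open(self.path, mode)
        if not append:
            for line in comments:
                self._fh.write(f"# {line}\n")
            self._fh.write("\t".join(self.columns) + "\n")

    def write_row(self, values: Sequence[float]) -> None:
        if len(values) != len(self.columns):
            raise ValueError("row length does not match header")
        it = int(values[0])
        rest = "\t".join(repr(float(v)) for v in values[1:])
        self._fh.write(f"{it}\t{rest}\n")

    def flush(self) -> None:
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_trace_log(path) -> pd.DataFrame:
    """Parse a BEAST-dialect trace log; '#' lines are comments.

    Raises ``ValueError`` naming the offending line for malformed
    headers, ragged rows, or a non-monotone Sample column.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "Sample":
                    raise ValueError(
                        f"{path}:{lineno}: header must start with 'Sample', got {fields[0]!r}"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {line!r}") from None
    if header is None:
        raise ValueError(f"{path}: no header row found")
    frame = pd.DataFrame(rows, columns=header)
    sample = frame["Sample"].to_numpy()
    if len(sample) > 1 and np.any(np.diff(sample) <= 0):
        bad = int(np.argmax(np.diff(sample) <= 0)) + 1
        raise ValueError(f"{path}: Sample column not strictly increasing at data row {bad + 1}")
    return frame


class NexusTreeWriter:
    """One-tree-per-sample NEXUS log with a translate block."""

    def __init__(self, path, taxa: Sequence[str], append: bool = False):
        self.path = Path(path)
        self.taxa = list(taxa)
        self._labels = {t: str(i + 1) for i, t in enumerate(self.taxa)}
        if append and self.path.exists():
            # drop the closing "End;" so new trees extend the trees block
            lines = self.path.read_text().splitlines()
            while lines and lines[-1].strip() in ("End;", ""):
                lines.pop()
            self.path.write_text("\n".join(lines) + "\n")
        self._fh = open(self.path, "a" if append else "w")
        if not append:
            n = len(self.taxa)
            lines = ["#NEXUS", "", "Begin taxa;", f"\tDimensions ntax={n};", "\t\tTaxlabels"]
            lines += [f"\t\t\t{t}" for t in self.taxa]
            lines += ["\t\t\t;", "End;", "Begin trees;", "\tTranslate"]
            lines += [
                f"\t\t{i + 1} {t}{',' if i < n - 1 else ''}"
                for i, t in enumerate(self.taxa)
            ]
            lines += ["\t\t\t;"]
            self._fh.write("\n".join(lines) + "\n")

    def add_tree(self, iteration: int, tree: Tree) -> None:
        if set(tree.taxa) != set(self.taxa):
            raise ValueError("tree taxa do not match the log's taxon set")
        self._fh.write(f"tree STATE_{iteration} = [&R] {tree.newick(self._labels)}\n")

    def close(self) -> None:
        self._fh.write("End;\n")
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_tree_log(path) -> list[Tree]:
    """Read a NEXUS tree log (translate block honoured) into Tree objects."""
    import dendropy

    trees = dendropy.TreeList.get(path=str(path), schema="nexus")
    taxa = sorted(t.label.replace(" ", "_") for t in trees.taxon_namespace)
    out = []
    for dtree in trees:
        out.append(Tree.from_newick(dtree.as_string(schema="newick").strip(), taxa=taxa))
    return out


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(alignment.sequence(t)), id=t, description="")
        for t in alignment.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    taxa = [r.id for r in records]
    return Alignment.from_sequences(taxa, [str(r.seq) for r in records])


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
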