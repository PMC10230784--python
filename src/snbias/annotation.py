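"""Per-gene polyA/length annotation from FASTA + GTF.

A gene's "full-length" sequence is taken as its genomic span on the
transcribed strand — the intron-inclusive gene body, ``end - start + 1``
nucleotides — because single-nucleus libraries capture nascent transcripts
whose internal (largely intronic) polyA stretches hybridize the polyT RT
primer. A polyA region is a maximal run of consecutive adenines strictly
longer than ``min_run`` (default 15, i.e. runs of >= 16 A).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "AnnotationParams",
    "SignatureSet",
    "LengthBins",
    "QUARTILE_LABELS",
    "count_polya_runs",
    "load_gene_models",
    "assign_length_quartiles",
    "build_length_bias_signature",
]

QUARTILE_LABELS = ["Short", "Short Med.", "Long Med.", "Long"]

_VALID = set("ACGTNacgtn")
_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class AnnotationParams:
    min_run: int = 15  # runs strictly longer than this count as polyA regions
    n_top: int = 200   # length-bias signature size

    def __post_init__(self):
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


@dataclass
class SignatureSet:
    """A named, ordered gene list for module scoring."""

    name: str
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")

    def __len__(self):
        return len(self.gene_ids)


@dataclass
class LengthBins:
    """Inner quartile boundaries and the four ordered bin labels."""

    edges: tuple[float, float, float]
    labels: list[str] = field(default_factory=lambda: list(QUARTILE_LABELS))

    def __post_init__(self):
        if not (self.edges[0] < self.edges[1] < self.edges[2]):
            raise ValueError("quartile edges must be strictly increasing")

    def label_of(self, length: float) -> str:
        """Right-closed bins: Short <= e1 < Short Med. <= e2 < ... < Long."""
        e1, e2, e3 = self.edges
        if length <= e1:
            return self.labels[0]
        if length <= e2:
            return self.labels[1]
        if length <= e3:
            return self.labels[2]
        return self.labels[3]


def count_polya_runs(sequence: str, min_run: int = 15) -> int:
    """Number of maximal runs of consecutive A (case-insensitive) strictly
    longer than ``min_run``. N breaks a run; any other character is an error.
    """
    bad = re.search(f"[^{''.join(sorted(_VALID))}]", sequence)
    if bad:
        raise ValueError(
            f"illegal character {bad.group()!r} at position {bad.start()}"
        )
    n = 0
    for m in re.finditer("[Aa]+", sequence):
        if m.end() - m.start() > min_run:
            n += 1
    return n


def _parse_gtf_genes(gtf_path) -> list[dict]:
    genes, seen = [], set()
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gtf_path}: malformed GTF line {lineno}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "gene":
                continue
            m = re.search(r'gene_id "([^"]+)"', attrs)
            if m is None:
                raise ValueError(f"{gtf_path}: line {lineno} lacks gene_id")
            gene_id = m.group(1)
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} in {gtf_path}")
            seen.add(gene_id)
            name = re.search(r'gene_name "([^"]+)"', attrs)
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{gtf_path}: non-integer coordinates, line {lineno}")
            if strand not in "+-":
                raise ValueError(f"{gtf_path}: bad strand {strand!r}, line {lineno}")
            if start_i > end_i or start_i < 1:
                raise ValueError(
                    f"{gtf_path}: invalid span {start_i}-{end_i}, line {lineno}"
                )
            genes.append(
                {
                    "gene_id": gene_id,
                    "symbol": name.group(1) if name else gene_id,
                    "chrom": chrom,
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                }
            )
    return genes


def load_gene_models(
    gtf_path, fasta_path, params: AnnotationParams | None = None
) -> pd.DataFrame:
    """Build the per-gene annotation table from a GTF and its genome FASTA.

    One row per GTF ``gene`` feature (1-based inclusive coordinates) with
    ``length_nt = end - start + 1`` and ``polya_count`` computed on the
    sense-strand gene-body sequence (reverse-complemented for minus-strand
    genes).
    """
    params = params or AnnotationParams()
    genes = _parse_gtf_genes(gtf_path)
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=False)
    rows = []
    for g in genes:
        if g["chrom"] not in fa:
            raise KeyError(
                f"contig {g['chrom']!r} (gene {g['gene_id']}) absent from FASTA"
            )
        contig_len = len(fa[g["chrom"]])
        if g["end"] > contig_len:
            raise ValueError(
                f"gene {g['gene_id']} span {g['start']}-{g['end']} exceeds "
                f"contig {g['chrom']} length {contig_len}"
            )
        seq = fa[g["chrom"]][g["start"] - 1 : g["end"]]
        if g["strand"] == "-":
            seq = seq.translate(_RC)[::-1]
        rows.append(
            {
                **g,
                "length_nt": g["end"] - g["start"] + 1,
                "polya_count": count_polya_runs(seq, params.min_run),
            }
        )
    return pd.DataFrame(rows)


def assign_length_quartiles(lengths) -> tuple[LengthBins, pd.Series]:
    """Quartile-bin genes by length.

    Edges are the empirical 25/50/75 percentiles (linear interpolation);
    bins are right-closed, so the top bin is open above its edge. Returns
    the bins and a label per gene (aligned to the input's index when it is
    a Series).
    """
    lengths = pd.Series(lengths, dtype=float)
    if len(lengths) < 4:
        raise ValueError("need at least 4 genes to form length quartiles")
    edges = tuple(np.percentile(lengths.to_numpy(), [25, 50, 75], method="linear"))
    if not (edges[0] < edges[1] < edges[2]):
        raise ValueError("degenerate length distribution: quartile edges collide")
    bins = LengthBins(edges)
    labels = lengths.map(bins.label_of)
    labels = pd.Series(
        pd.Categorical(labels, categories=QUARTILE_LABELS, ordered=True),
        index=lengths.index,
        name="length_bin",
    )
    return bins, labels


def build_length_bias_signature(
    models: pd.DataFrame, params: AnnotationParams | None = None
) -> SignatureSet:
    """The top-N genes by internal polyA-run count.

    Ties on polyA count are broken by gene length (longer first), then by
    gene id, so the signature is a deterministic function of the annotation.
    """
    params = params or AnnotationParams()
    if len(models) < params.n_top:
        raise ValueError(
            f"universe has {len(models)} genes, fewer than n_top={params.n_top}"
        )
    ordered = models.sort_values(
        ["polya_count", "length_nt", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return SignatureSet("length_bias", ordered["gene_id"].head(params.n_top).tolist())
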