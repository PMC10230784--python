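"""Plain-text readers/writers for signatures, gene tables and collections."""

from __future__ import annotations

import pandas as pd

from .annotation import SignatureSet

__all__ = [
    "read_signature",
    "write_signature",
    "read_signature_collection",
    "write_gene_table",
    "read_gene_table",
]


def read_signature(path, name: str | None = None) -> SignatureSet:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return SignatureSet(name, genes)


def write_signature(sig: SignatureSet, path) -> None:
    with open(path, "w") as fh:
        for g in sig.gene_ids:
            fh.write(g + "\n")


def read_signature_collection(path) -> list[SignatureSet]:
    """Two-column TSV (set name, gene id) -> list of SignatureSets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return [
        SignatureSet(str(name), list(dict.fromkeys(sub["gene"].astype(str))))
        for name, sub in df.groupby("set", sort=True)
    ]


def write_gene_table(models: pd.DataFrame, path) -> None:
    models.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
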