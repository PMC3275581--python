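"""Plain-text TSV interchange with provenance header comments."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv"]


def write_tsv(frame: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    """Write a TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`; header comments are skipped
    but returned in ``frame.attrs['meta']``."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition(":")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t", index_col=index_col)
    frame.attrs["meta"] = meta
    return frame
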