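"""Count-table container and file dialects for zOTU data.

A :class:`ZotuTable` holds mice-by-zOTU integer counts. Two on-disk dialects
are supported: plain TSV (rows = zOTUs, columns = mouse IDs, matching the
common ``usearch``/QIIME "classic" layout) and minimal BIOM v1 (JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ZotuTable", "read_zotu_tsv", "read_zotu_biom"]


@dataclass
class ZotuTable:
    """Mice x zOTU integer count matrix.

    Parameters
    ----------
    mouse_ids : list of str
        Unique sample identifiers (rows).
    zotu_ids : list of str
        Unique zOTU identifiers (columns).
    counts : ndarray of int, shape (n_mice, n_zotus)
        Non-negative read counts.
    """

    mouse_ids: list[str]
    zotu_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.mouse_ids), len(self.zotu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.mouse_ids)} mice x {len(self.zotu_ids)} zOTUs"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if len(set(self.mouse_ids)) != len(self.mouse_ids):
            raise ValueError("mouse_ids must be unique")
        if len(set(self.zotu_ids)) != len(self.zotu_ids):
            raise ValueError("zotu_ids must be unique")

    @property
    def depth(self) -> np.ndarray:
        """Per-mouse total read count (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_mice(self) -> int:
        return len(self.mouse_ids)

    @property
    def n_zotus(self) -> int:
        return len(self.zotu_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as zOTU-by-mouse DataFrame (classic layout)."""
        return pd.DataFrame(
            self.counts.T, index=self.zotu_ids, columns=self.mouse_ids
        )

    def subset(self, mouse_ids: list[str]) -> "ZotuTable":
        idx = [self.mouse_ids.index(m) for m in mouse_ids]
        return ZotuTable(list(mouse_ids), list(self.zotu_ids), self.counts[idx])

    # ---------------------------------------------------------------- I/O
    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "#zOTU ID"
        df.to_csv(path, sep="\t")

    def write_biom(self, path) -> None:
        """Write as BIOM format v1.0 (dense JSON)."""
        obj = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "diopower",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [self.n_zotus, self.n_mice],
            "rows": [{"id": z, "metadata": None} for z in self.zotu_ids],
            "columns": [{"id": m, "metadata": None} for m in self.mouse_ids],
            "data": self.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def read_zotu_tsv(path) -> ZotuTable:
    """Read a classic zOTU TSV (rows = zOTUs, columns = mice)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ZotuTable(
        list(df.columns), list(df.index.astype(str)), df.to_numpy().T
    )


def read_zotu_biom(path) -> ZotuTable:
    """Read a BIOM v1.0 JSON table (dense or sparse)."""
    with open(path) as fh:
        obj = json.load(fh)
    n_rows, n_cols = obj["shape"]
    zotu_ids = [r["id"] for r in obj["rows"]]
    mouse_ids = [c["id"] for c in obj["columns"]]
    if obj["matrix_type"] == "dense":
        mat = np.asarray(obj["data"])
    else:
        mat = np.zeros((n_rows, n_cols))
        for i, j, v in obj["data"]:
            mat[int(i), int(j)] = v
    return ZotuTable(mouse_ids, zotu_ids, mat.T)
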