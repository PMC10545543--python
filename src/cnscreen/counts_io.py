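"""Count-matrix and metadata I/O, plus anchored guide extraction from FASTQ.

The count table follows the MAGeCK convention: a header row
``sgRNA<TAB>gene`` followed by one column per sample, integer counts.
Sample metadata is a separate TSV ``sample_id<TAB>tissue<TAB>replicate``.

Guide counting from raw reads uses the vector's constant anchor (the 5'
scaffold ends in ``CACCG`` immediately before the 20-nt protospacer): the
first anchor occurrence is located in each read and the following 20 nt are
matched against the manifest. This sidesteps demultiplexing/trimming and is
robust to staggered-primer offsets.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParseError
from .library import LibraryManifest

TISSUES = ("blood", "spleen", "meninges", "parenchyma", "lymph_node", "input")


@dataclass
class CountMatrix:
    """Integer sgRNA x sample counts with tissue/replicate annotation.

    counts
        DataFrame indexed by sgrna_id, one integer column per sample_id.
    targets
        Series mapping sgrna_id -> target_id (aligned with ``counts.index``).
    meta
        DataFrame indexed by sample_id with columns ``tissue`` and
        ``replicate``; (tissue, replicate) pairs are unique.
    """

    counts: pd.DataFrame
    targets: pd.Series
    meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()]
            raise FormatError(f"duplicate sgrna_id(s): {list(dupes[:5])}")
        if self.counts.shape[1] == 0:
            raise FormatError("count matrix has no sample columns")
        if not all(np.issubdtype(dt, np.integer) for dt in self.counts.dtypes):
            raise FormatError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        self.targets = self.targets.reindex(self.counts.index)
        if self.targets.isna().any():
            missing = self.counts.index[self.targets.isna()]
            raise FormatError(f"sgRNAs without a target mapping: {list(missing[:5])}")
        if self.meta is not None:
            self._check_meta()

    def _check_meta(self):
        meta = self.meta
        for col in ("tissue", "replicate"):
            if col not in meta.columns:
                raise FormatError(f"sample metadata missing column {col!r}")
        unknown = [s for s in self.counts.columns if s not in meta.index]
        if unknown:
            raise FormatError(f"samples without metadata: {unknown[:5]}")
        sub = meta.loc[list(self.counts.columns)]
        if sub[["tissue", "replicate"]].duplicated().any():
            raise FormatError("(tissue, replicate) pairs must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, tissue: str) -> list[str]:
        """Sample ids of a tissue, ordered by replicate number."""
        if self.meta is None:
            raise FormatError("no sample metadata attached")
        sub = self.meta.loc[self.meta["tissue"] == tissue]
        sub = sub.loc[sub.index.intersection(self.counts.columns)]
        return list(sub.sort_values("replicate").index)

    def nt_ids(self) -> list[str]:
        from .library import NT_TARGET_ID

        return list(self.counts.index[self.targets == NT_TARGET_ID])


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene", cm.targets.values)
    out.index.name = "sgRNA"
    out.to_csv(path, sep="\t")


def read_counts(
    path,
    meta=None,
    manifest: LibraryManifest | None = None,
) -> CountMatrix:
    """Read a MAGeCK-style count TSV.

    ``meta`` may be a path to a metadata TSV or a pre-built DataFrame. If a
    manifest is supplied, sgRNAs absent from it are reported via a
    ``FormatError`` rather than silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sgRNA", "gene"]:
        raise FormatError(
            f"{path}: expected header 'sgRNA<TAB>gene<TAB><samples...>', "
            f"got {list(df.columns[:3])}"
        )
    sample_cols = list(df.columns[2:])
    counts = {}
    for col in sample_cols:
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric count in column {col!r}: {exc}") from exc
        frac = vals % 1 != 0
        if frac.any():
            row = df.loc[frac.idxmax(), "sgRNA"]
            raise ParseError(
                f"{path}: non-integer count at sgRNA {row!r}, column {col!r}"
            )
        counts[col] = vals.astype(np.int64)
    counts = pd.DataFrame(counts)
    counts.index = pd.Index(df["sgRNA"], name="sgRNA")
    targets = pd.Series(df["gene"].values, index=counts.index, name="target_id")
    if manifest is not None:
        unknown = counts.index.difference(manifest.sgrna_ids)
        if len(unknown):
            raise FormatError(
                f"{path}: {len(unknown)} sgRNA(s) not in manifest, e.g. {list(unknown[:5])}"
            )
    meta_df = read_sample_meta(meta) if isinstance(meta, (str,)) or hasattr(meta, "__fspath__") else meta
    return CountMatrix(counts=counts, targets=targets, meta=meta_df)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index() if meta.index.name == "sample_id" else meta
    out.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    for col in ("sample_id", "tissue", "replicate"):
        if col not in meta.columns:
            raise FormatError(f"{path}: metadata missing column {col!r}")
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise FormatError(f"{path}: replicate numbers must be >= 1")
    return meta.set_index("sample_id")


def _open_maybe_gzip(path):
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(fh, "rt")
    return open(path, "rt")


def count_guides(
    fastq_path,
    manifest: LibraryManifest,
    anchor: str = "CACCG",
    max_mismatch: int = 0,
) -> tuple[pd.Series, dict]:
    """Count guides in a demultiplexed single-end FASTQ.

    For each read the first occurrence of ``anchor`` is located and the 20 nt
    that follow are matched against the manifest guide sequences (exactly, or
    within ``max_mismatch`` Hamming mismatches when > 0). Returns a per-sgRNA
    count Series (manifest order) and a stats dict with ``n_reads``,
    ``n_anchored`` and ``n_mapped``.
    """
    guide_len = 20
    exact = dict(zip(manifest.records["guide_seq"], manifest.records["sgrna_id"]))
    seqs = manifest.records["guide_seq"].tolist()
    ids = manifest.records["sgrna_id"].tolist()
    counts = pd.Series(0, index=manifest.sgrna_ids, name="count", dtype=np.int64)
    n_reads = n_anchored = n_mapped = 0
    with _open_maybe_gzip(fastq_path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            n_reads += 1
            read = str(rec.seq).upper()
            pos = read.find(anchor)
            if pos < 0:
                continue
            n_anchored += 1
            cand = read[pos + len(anchor): pos + len(anchor) + guide_len]
            if len(cand) < guide_len:
                continue
            hit = exact.get(cand)
            if hit is None and max_mismatch > 0:
                best, best_d = None, max_mismatch + 1
                for gid, gs in zip(ids, seqs):
                    d = sum(a != b for a, b in zip(cand, gs))
                    if d < best_d:
                        best, best_d = gid, d
                        if d == 0:
                            break
                if best_d <= max_mismatch:
                    hit = best
            if hit is not None:
                counts[hit] += 1
                n_mapped += 1
    stats = {"n_reads": n_reads, "n_anchored": n_anchored, "n_mapped": n_mapped}
    return counts, stats
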