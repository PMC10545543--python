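"""sgRNA library representation and screen-design arithmetic.

A pooled CRISPR screen is defined by its guide library: for each targeted
gene (or miRNA) a handful of 20-nt single guide RNAs, plus a pool of
non-targeting (NT) control guides that define the empirical null. This
module holds the library manifest and the back-of-envelope design numbers a
screener works with: how many transduced cells are needed for a given
coverage, what coverage a transduction actually achieves, and what fraction
of transduced cells carry more than one guide at a given MOI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

#: Reserved target id shared by every non-targeting control guide.
NT_TARGET_ID = "non-targeting"

TARGET_TYPES = ("gene", "mirna", "nt")

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MANIFEST_COLUMNS = ["sgrna_id", "target_id", "target_type", "guide_seq"]


class LibraryManifest:
    """The sgRNA universe of a screen.

    Wraps a DataFrame with columns ``sgrna_id``, ``target_id``,
    ``target_type`` (gene|mirna|nt) and ``guide_seq`` (20-nt uppercase DNA),
    validated on construction.
    """

    def __init__(self, records: pd.DataFrame):
        records = records.reset_index(drop=True)
        missing = [c for c in MANIFEST_COLUMNS if c not in records.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        records = records[MANIFEST_COLUMNS].copy()
        if len(records) == 0:
            raise DesignError("manifest has zero records")
        if records["sgrna_id"].duplicated().any():
            dupes = records.loc[records["sgrna_id"].duplicated(), "sgrna_id"]
            raise FormatError(f"duplicate sgrna_id(s): {list(dupes[:5])}")
        bad_type = ~records["target_type"].isin(TARGET_TYPES)
        if bad_type.any():
            raise FormatError(
                f"invalid target_type(s): {sorted(records.loc[bad_type, 'target_type'].unique())}"
            )
        seqs = records["guide_seq"]
        bad_seq = ~seqs.str.fullmatch(r"[ACGT]{20}")
        if bad_seq.any():
            raise FormatError(
                f"guide_seq must be 20-nt A/C/G/T; offending sgrna_id(s): "
                f"{list(records.loc[bad_seq, 'sgrna_id'][:5])}"
            )
        nt = records["target_type"] == "nt"
        if nt.any() and (records.loc[nt, "target_id"] != NT_TARGET_ID).any():
            raise FormatError(
                f"all NT records must use the reserved target_id {NT_TARGET_ID!r}"
            )
        if (~nt & (records["target_id"] == NT_TARGET_ID)).any():
            raise FormatError(
                f"target_id {NT_TARGET_ID!r} is reserved for NT guides"
            )
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.records["sgrna_id"])

    @property
    def nt_ids(self) -> list[str]:
        """sgRNA ids of the non-targeting control guides."""
        mask = self.records["target_type"] == "nt"
        return self.records.loc[mask, "sgrna_id"].tolist()

    @property
    def targets(self) -> pd.Series:
        """Mapping sgrna_id -> target_id."""
        return self.records.set_index("sgrna_id")["target_id"]

    def guides_per_target(self) -> pd.Series:
        """Number of guides per target_id (NT pool counted under its shared id)."""
        return self.records.groupby("target_id").size()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LibraryManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, LibraryManifest) and self.records.equals(other.records)


@dataclass(frozen=True)
class ScreenDesign:
    """Headline numbers of a screen design.

    n_cells
        T cells put into transduction.
    moi
        Multiplicity of infection, in (0, 1]; kept low (< 0.3 in practice) so
        most transduced cells carry a single guide.
    library_size
        Number of distinct sgRNAs.
    target_coverage
        Desired transduced cells per sgRNA.
    """

    n_cells: int
    moi: float
    library_size: int
    target_coverage: float

    def __post_init__(self):
        for name in ("n_cells", "moi", "library_size", "target_coverage"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be strictly positive")


def _random_unique_guides(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unique random 20-mers over ACGT (rejection sampling on duplicates)."""
    if n > 4**20:
        raise DesignError("cannot draw more unique 20-mers than exist")
    seen: set[bytes] = set()
    out: list[bytes] = []
    while len(out) < n:
        draw = _BASES[rng.integers(0, 4, size=(n - len(out), 20))]
        for row in draw.view("S20").ravel():
            if row not in seen:
                seen.add(row)
                out.append(row)
    return np.array([s.decode() for s in out])


def build_manifest(
    n_genes: int,
    sgrnas_per_gene: int = 4,
    n_nt: int = 800,
    n_mirna: int = 0,
    seed: int = 0,
    total: int | None = None,
) -> LibraryManifest:
    """Construct a synthetic library manifest.

    Generates ``n_genes * sgrnas_per_gene + n_mirna * sgrnas_per_gene + n_nt``
    records with unique random guide sequences. ``total``, if given, trims the
    targeting portion (genes, then miRNAs) to an exact overall record count;
    real libraries often fall short of the nominal guides-per-target for some
    targets, and published totals are ambiguous about whether NT guides are
    included, so both readings are constructible.
    """
    for name, v in (
        ("n_genes", n_genes), ("sgrnas_per_gene", sgrnas_per_gene),
        ("n_nt", n_nt), ("n_mirna", n_mirna),
    ):
        if v < 0:
            raise DesignError(f"{name} must be >= 0")
    if n_genes + n_nt < 1:
        raise DesignError("need at least one gene or NT guide")
    n_records = (n_genes + n_mirna) * sgrnas_per_gene + n_nt
    if n_records == 0:
        raise DesignError("design yields zero records")
    if total is not None:
        if total > n_records:
            raise DesignError("total exceeds the untrimmed record count")
        if total < n_nt + n_genes + n_mirna:
            raise DesignError("total leaves some targets without any guide")
        n_records = total

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []  # sgrna_id, target_id, target_type
    for g in range(n_genes):
        tid = f"gene{g + 1:05d}"
        for k in range(sgrnas_per_gene):
            rows.append((f"{tid}_sg{k + 1}", tid, "gene"))
    for m in range(n_mirna):
        tid = f"mir{m + 1:04d}"
        for k in range(sgrnas_per_gene):
            rows.append((f"{tid}_sg{k + 1}", tid, "mirna"))
    if total is not None and len(rows) > n_records - n_nt:
        # Trim whole guides off the tail targets, round-robin from the last
        # guide index downwards, so every target keeps >= 1 guide.
        excess = len(rows) - (n_records - n_nt)
        df = pd.DataFrame(rows, columns=["sgrna_id", "target_id", "target_type"])
        order = df.groupby("target_id").cumcount()
        drop_idx = df.index[np.lexsort((df.index, -order.values))][:excess]
        kept = df.drop(index=drop_idx)
        if (kept.groupby("target_id").size() < 1).any():
            raise DesignError("trimming removed every guide of a target")
        rows = list(kept.itertuples(index=False, name=None))
    for k in range(n_nt):
        rows.append((f"nt_sg{k + 1}", NT_TARGET_ID, "nt"))

    df = pd.DataFrame(rows, columns=["sgrna_id", "target_id", "target_type"])
    df["guide_seq"] = _random_unique_guides(len(df), rng)
    return LibraryManifest(df)


def plan_coverage(library_size: int, target_coverage: int) -> int:
    """Cells needed to hit ``target_coverage`` cells per sgRNA: exact product."""
    if library_size < 1 or target_coverage < 1:
        raise DesignError("library_size and target_coverage must be >= 1")
    return int(library_size) * int(target_coverage)


def expected_coverage(n_cells: float, moi: float, library_size: int) -> float:
    """Transduced cells per sgRNA achieved by a design.

    ``n_cells * moi`` cells receive a guide; divided over the library this is
    the realised coverage (e.g. 300e6 cells at MOI 0.3 over ~88k guides gives
    roughly 1,000x).
    """
    if not (0 < moi <= 1):
        raise DesignError("moi must lie in (0, 1]")
    if n_cells < 1 or library_size < 1:
        raise DesignError("n_cells and library_size must be >= 1")
    return n_cells * moi / library_size


def multi_integration_fraction(moi: float) -> float:
    """Fraction of *transduced* cells with more than one integration.

    Under a Poisson(moi) model for integrations per cell:
    ``(1 - e^-m - m e^-m) / (1 - e^-m)``; tends to 0 as moi -> 0 and
    increases monotonically in moi.
    """
    if moi <= 0:
        raise DesignError("moi must be > 0")
    em = math.exp(-moi)
    return (1.0 - em - moi * em) / (1.0 - em)
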