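"""Tabular I/O for SNP panels, allele counts and cohort metadata.

All on-disk formats are UTF-8 tab-separated files with a fixed header:

``panel``
    ``snp_id  chrom  pos  ref  alt  adaptive  is_transition``
``counts``
    ``individual_id  snp_id  n_adaptive  n_total``
``metadata``
    ``individual_id  date_bp  group  region``

Positions are 1-based (VCF/mpileup convention). Chromosome names must match
verbatim between panel and pileup input — no "chr" prefix normalisation is
attempted. A missing (individual, SNP) row in a counts table means zero
coverage at that site, not missing data of any other kind; writers omit
all-zero rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "SNPPanel",
    "AlleleCounts",
    "CohortMetadata",
    "PanelIOError",
    "MODERN",
    "load_panel",
    "write_panel",
    "load_counts",
    "write_counts",
    "load_metadata",
    "write_metadata",
    "counts_from_mpileup",
]

#: Sentinel date label for present-day individuals.
MODERN = "modern"

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "adaptive", "is_transition"]
COUNT_COLUMNS = ["individual_id", "snp_id", "n_adaptive", "n_total"]
META_COLUMNS = ["individual_id", "date_bp", "group", "region"]

_NUCLEOTIDES = frozenset("ACGT")
_TRUE_STRINGS = {"true", "1", "t", "yes"}
_FALSE_STRINGS = {"false", "0", "f", "no"}


class PanelIOError(ValueError):
    """Raised on malformed or invariant-violating input tables."""


def _dedent_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    df.columns = [str(c) for c in df.columns]
    return df


@dataclass
class SNPPanel:
    """Ordered set of panel SNPs with alleles and adaptive-allele designation.

    The adaptive allele is the one carried by the focal (selected) haplotype
    at each site; it must equal either ``ref`` or ``alt``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = _dedent_frame(self.df)
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelIOError(f"panel table missing columns: {missing}")
        df = df[PANEL_COLUMNS].copy()
        df["snp_id"] = df["snp_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(np.int64)
        for col in ("ref", "alt", "adaptive"):
            df[col] = df[col].astype(str).str.upper()
        df["is_transition"] = df["is_transition"].map(_coerce_bool)
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise PanelIOError(f"duplicate snp_id values in panel: {dups}")
        if (df["pos"] < 1).any():
            raise PanelIOError("panel positions must be >= 1 (1-based)")
        for col in ("ref", "alt", "adaptive"):
            bad = ~df[col].isin(_NUCLEOTIDES)
            if bad.any():
                raise PanelIOError(
                    f"non-nucleotide {col} allele(s): {df.loc[bad, col].tolist()}"
                )
        if (df["ref"] == df["alt"]).any():
            raise PanelIOError("panel has sites with ref == alt")
        bad = ~(df["adaptive"].eq(df["ref"]) | df["adaptive"].eq(df["alt"]))
        if bad.any():
            raise PanelIOError(
                "adaptive allele must equal ref or alt at: "
                f"{df.loc[bad, 'snp_id'].tolist()}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SNPPanel):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def site_index(self) -> dict[tuple[str, int], pd.Series]:
        """Map (chrom, pos) -> panel row, for pileup conversion."""
        return {
            (row.chrom, int(row.pos)): row
            for row in self.df.itertuples(index=False)
        }


def _coerce_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise PanelIOError(f"cannot interpret is_transition value {value!r}")


@dataclass
class AlleleCounts:
    """Per (individual, SNP) reads supporting the adaptive allele and in total."""

    df: pd.DataFrame
    panel: SNPPanel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = _dedent_frame(self.df)
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise PanelIOError(f"counts table missing columns: {missing}")
        df = df[COUNT_COLUMNS].copy()
        df["individual_id"] = df["individual_id"].astype(str)
        df["snp_id"] = df["snp_id"].astype(str)
        for col in ("n_adaptive", "n_total"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        if (df["n_adaptive"] < 0).any() or (df["n_total"] < 0).any():
            raise PanelIOError("negative read counts")
        bad = df["n_adaptive"] > df["n_total"]
        if bad.any():
            rows = df.loc[bad, ["individual_id", "snp_id"]].to_records(index=False)
            raise PanelIOError(f"n_adaptive > n_total at {list(rows)}")
        if df.duplicated(subset=["individual_id", "snp_id"]).any():
            dup = df.loc[
                df.duplicated(subset=["individual_id", "snp_id"]),
                ["individual_id", "snp_id"],
            ]
            raise PanelIOError(
                f"duplicate (individual_id, snp_id) rows: {dup.to_records(index=False)}"
            )
        if self.panel is not None:
            known = set(self.panel.snp_ids)
            unknown = sorted(set(df["snp_id"]) - known)
            if unknown:
                raise PanelIOError(f"counts reference SNPs absent from panel: {unknown}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCounts):
            return NotImplemented
        a = self.df.sort_values(["individual_id", "snp_id"]).reset_index(drop=True)
        b = other.df.sort_values(["individual_id", "snp_id"]).reset_index(drop=True)
        return a.equals(b)

    @property
    def individual_ids(self) -> list[str]:
        return sorted(self.df["individual_id"].unique())


@dataclass
class CohortMetadata:
    """Per-individual dates (cal B.P. or ``modern``), group and region labels."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = _dedent_frame(self.df)
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise PanelIOError(f"metadata table missing columns: {missing}")
        df = df[META_COLUMNS].copy()
        df["individual_id"] = df["individual_id"].astype(str)
        df["group"] = df["group"].astype(str)
        df["region"] = df["region"].astype(str)
        dates = []
        for raw in df["date_bp"]:
            if isinstance(raw, str) and raw.strip().lower() == MODERN:
                dates.append(MODERN)
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise PanelIOError(f"unparseable date_bp value {raw!r}") from exc
            if value < 0:
                raise PanelIOError(f"negative date_bp {value}")
            dates.append(value)
        df["date_bp"] = dates
        if df["individual_id"].duplicated().any():
            dup = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
            raise PanelIOError(f"duplicate individual_id values: {dup}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortMetadata):
            return NotImplemented
        a = self.df.sort_values("individual_id").reset_index(drop=True)
        b = other.df.sort_values("individual_id").reset_index(drop=True)
        return a.equals(b)

    @property
    def individual_ids(self) -> list[str]:
        return self.df["individual_id"].tolist()


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise PanelIOError(f"malformed table {path}: {exc}") from exc


def load_panel(path: Union[str, Path]) -> SNPPanel:
    """Load and validate a SNP panel table; row order is preserved."""
    return SNPPanel(_read_tsv(path))


def write_panel(panel: SNPPanel, path: Union[str, Path]) -> None:
    df = panel.df.copy()
    df["is_transition"] = df["is_transition"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


def load_counts(path: Union[str, Path], panel: SNPPanel | None = None) -> AlleleCounts:
    """Load a counts table, validating against ``panel`` when given.

    (individual, SNP) pairs absent from the file are zero coverage by
    convention; no row is required for them.
    """
    return AlleleCounts(_read_tsv(path), panel=panel)


def write_counts(counts: AlleleCounts, path: Union[str, Path]) -> None:
    """Write a counts table; all-zero rows are omitted (zero coverage is implicit)."""
    df = counts.df
    df = df[(df["n_total"] > 0) | (df["n_adaptive"] > 0)]
    df.to_csv(path, sep="\t", index=False)


def load_metadata(path: Union[str, Path]) -> CohortMetadata:
    return CohortMetadata(_read_tsv(path))


def write_metadata(meta: CohortMetadata, path: Union[str, Path]) -> None:
    meta.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# samtools-mpileup conversion


def _tokenize_pileup_bases(bases: str, line_no: int) -> list[str]:
    """Expand an mpileup base string into one token per aligned position.

    Read-start markers (``^`` + mapping-quality char), read-end markers
    (``$``) and indel descriptions (``[+-]N<seq>``) are consumed without
    emitting a token; every other symbol (including ``*``, ``<``, ``>``)
    pairs with one base-quality character.
    """
    out: list[str] = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PanelIOError(
                    f"line {line_no}: dangling read-start marker in base string"
                )
            i += 2
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PanelIOError(
                    f"line {line_no}: indel marker without length at column {i}"
                )
            length = int(bases[i + 1 : j])
            i = j + length
        else:
            out.append(c)
            i += 1
    return out


def counts_from_mpileup(
    pileup: Union[str, Path, IO[str], Iterable[str]],
    panel: SNPPanel,
    individual_id: str = "sample",
    min_base_quality: int = 30,
    strict_biallelic: bool = False,
) -> AlleleCounts:
    """Convert single-sample samtools-mpileup text into panel allele counts.

    Per panel site, bases with Phred quality >= ``min_base_quality``
    (Phred+33) are retained. ``n_adaptive`` counts retained bases equal to
    the adaptive allele, case-insensitively; ``.``/``,`` resolve to the
    pileup reference base. ``n_total`` counts all retained A/C/G/T bases
    (with ``strict_biallelic`` only the panel's ref/alt alleles). Deletion
    placeholders (``*``), reference skips (``<``/``>``) and N bases are
    excluded from both counts.

    The mapping-quality filter (MQ >= 30 upstream) and any end-masking of
    damaged read termini must be applied when the pileup is produced:
    read-relative positions are not recoverable from mpileup text.
    """
    if isinstance(pileup, Path):
        handle: Iterable[str] = io.StringIO(pileup.read_text())
    elif isinstance(pileup, str):
        # a str is pileup text, not a path; pass a Path to read a file
        handle = io.StringIO(pileup)
    else:
        handle = pileup

    sites = panel.site_index()
    rows: list[dict[str, object]] = []
    for line_no, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PanelIOError(
                f"line {line_no}: expected 6 mpileup columns, got {len(fields)}"
            )
        chrom, pos_s, ref_base, _depth, bases, quals = fields[:6]
        key = (chrom, int(pos_s))
        site = sites.get(key)
        if site is None:
            continue
        tokens = _tokenize_pileup_bases(bases, line_no)
        if len(tokens) != len(quals):
            raise PanelIOError(
                f"line {line_no}: {len(tokens)} aligned bases but "
                f"{len(quals)} quality characters"
            )
        ref_base = ref_base.upper()
        adaptive = site.adaptive
        allowed = {site.ref, site.alt} if strict_biallelic else _NUCLEOTIDES
        n_adaptive = 0
        n_total = 0
        for token, qchar in zip(tokens, quals):
            if token in "*<>":
                continue
            base = ref_base if token in ".," else token.upper()
            if base not in _NUCLEOTIDES or base not in allowed:
                continue
            if ord(qchar) - 33 < min_base_quality:
                continue
            n_total += 1
            if base == adaptive:
                n_adaptive += 1
        rows.append(
            {
                "individual_id": individual_id,
                "snp_id": site.snp_id,
                "n_adaptive": n_adaptive,
                "n_total": n_total,
            }
        )

    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return AlleleCounts(df, panel=panel)
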