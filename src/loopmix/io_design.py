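"""Tabular formats for loop-design two-color experiments.

A design file has two tab-delimited sections::

    [channels]
    array   dye     sample  group
    a01     Cy3     s01     haplo
    ...
    [spots]
    spot    transcript      duplicate_index block
    t0001.1 t0001   1       b1
    ...

Intensity tables are GPR-like long format (spot, array, dye, intensity);
missing cells are written as ``NA``.  All files are UTF-8, tab-delimited,
with ``#`` comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DYES = ("Cy3", "Cy5")

CHANNEL_COLUMNS = ["array", "dye", "sample", "group"]
SPOT_COLUMNS = ["spot", "transcript", "duplicate_index", "block"]
INTENSITY_COLUMNS = ["spot", "array", "dye", "intensity"]


class FormatError(ValueError):
    """A file or table violates the declared format."""


class DesignError(ValueError):
    """A design is structurally invalid for the requested analysis."""


def _canonical_dye(token: str, context: str = "") -> str:
    t = str(token).strip().lower()
    if t == "cy3":
        return "Cy3"
    if t == "cy5":
        return "Cy5"
    raise FormatError(f"unknown dye token {token!r}{context}")


@dataclass
class ArrayDesign:
    """Channel map and spot layout of a two-color hybridization experiment.

    ``channels`` has one row per hybridized sample-channel with columns
    (array, dye, sample, group); ``spots`` has one row per physical spot
    with columns (spot, transcript, duplicate_index, block).
    """

    channels: pd.DataFrame
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        self.channels = pd.DataFrame(self.channels, columns=CHANNEL_COLUMNS).copy()
        self.spots = pd.DataFrame(self.spots, columns=SPOT_COLUMNS).copy()
        self.channels["dye"] = [_canonical_dye(d) for d in self.channels["dye"]]
        self.spots["duplicate_index"] = self.spots["duplicate_index"].astype(int)
        self.validate()

    # ---- structure ----

    @property
    def n_arrays(self) -> int:
        return self.channels["array"].nunique()

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def arrays(self) -> list:
        return list(dict.fromkeys(self.channels["array"]))

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.channels["group"]))

    @property
    def transcripts(self) -> list:
        return list(dict.fromkeys(self.spots["transcript"]))

    def validate(self) -> None:
        ch = self.channels
        dup = ch.duplicated(subset=["array", "dye"])
        if dup.any():
            row = ch[dup].iloc[0]
            raise DesignError(
                f"duplicate channel: array {row['array']!r} listed twice with dye {row['dye']!r}"
            )
        per_array = ch.groupby("array")["dye"].nunique()
        # an array may have an unused channel (odd sample totals), but never
        # two channels with the same dye (caught above) or more than two rows
        counts = ch.groupby("array").size()
        if (counts > 2).any():
            bad = counts[counts > 2].index[0]
            raise DesignError(f"array {bad!r} has more than two channels")
        del per_array
        if ch["sample"].duplicated().any():
            bad = ch.loc[ch["sample"].duplicated(), "sample"].iloc[0]
            raise DesignError(f"sample {bad!r} assigned to more than one channel")
        if self.spots["duplicate_index"].min() < 1:
            raise DesignError("duplicate_index must be >= 1")
        if self.spots["spot"].duplicated().any():
            bad = self.spots.loc[self.spots["spot"].duplicated(), "spot"].iloc[0]
            raise DesignError(f"spot id {bad!r} declared twice")

    @property
    def loop_connected(self) -> bool:
        """True when the samples form a single cycle through shared arrays.

        Reported for information only: designs in which each sample occupies
        a single channel (one array, one dye) are pairings, not cycles, and
        are perfectly legal.
        """
        ch = self.channels
        if ch.empty:
            return False
        # samples are nodes; two samples on the same array are adjacent
        adj: dict = {s: set() for s in ch["sample"]}
        for _, grp in ch.groupby("array"):
            samples = list(grp["sample"])
            for a in samples:
                for b in samples:
                    if a != b:
                        adj[a].add(b)
        if len(adj) == 2:
            # two co-hybridized samples: the degenerate 2-cycle
            return all(len(v) == 1 for v in adj.values())
        if any(len(v) != 2 for v in adj.values()):
            return False
        # connected 2-regular graph <=> single cycle
        seen = set()
        stack = [next(iter(adj))]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj[node])
        return len(seen) == len(adj)

    def dye_balance(self) -> pd.DataFrame:
        """Per-group Cy3/Cy5 channel counts (the dye-swap bookkeeping)."""
        return (
            self.channels.groupby(["group", "dye"]).size().unstack(fill_value=0)
        )

    def spot_to_transcript(self) -> pd.Series:
        return self.spots.set_index("spot")["transcript"]


@dataclass
class IntensityMatrix:
    """Per-(spot, array, dye) raw intensities in long format.

    ``values`` columns are (spot, array, dye, intensity); a NaN intensity is
    an explicitly MISSING cell.  Intensities are non-negative.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values, columns=INTENSITY_COLUMNS).copy()
        self.values["intensity"] = self.values["intensity"].astype(float)
        v = self.values["intensity"]
        if (v.dropna() < 0).any():
            bad = v.dropna()[v.dropna() < 0].iloc[0]
            raise FormatError(f"negative intensity {bad}")

    @property
    def n_present(self) -> int:
        return int(self.values["intensity"].notna().sum())

    @property
    def n_missing(self) -> int:
        return int(self.values["intensity"].isna().sum())

    def pivot(self) -> pd.DataFrame:
        """Wide view: rows = spots, columns = (array, dye) channels."""
        return self.values.pivot_table(
            index="spot", columns=["array", "dye"], values="intensity",
            dropna=False, aggfunc="first",
        )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy())


# The log2-transformed matrix has the same long layout; the distinct type
# documents which stage a table came from.
class ExpressionMatrix(IntensityMatrix):
    """Log2-scale expression values (or normalization residuals)."""

    def __post_init__(self) -> None:  # log2 values may be negative
        self.values = pd.DataFrame(self.values, columns=INTENSITY_COLUMNS).copy()
        self.values["intensity"] = self.values["intensity"].astype(float)


@dataclass
class AnnotationMap:
    """Gene -> term and term -> ancestor (slim) mappings over a gene universe."""

    gene_terms: dict = field(default_factory=dict)   # gene -> set of terms
    slim: dict = field(default_factory=dict)         # term -> set of ancestors
    universe: set = field(default_factory=set)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for term, ancestors in self.slim.items():
            if term in ancestors:
                raise FormatError(f"slim map has a self-loop at term {term!r}")
        outside = set(self.gene_terms) - set(self.universe)
        if outside:
            raise FormatError(
                f"annotated genes outside the universe: {sorted(outside)[:5]}"
            )

    @property
    def terms(self) -> set:
        out: set = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out

    def genes_for_term(self, term) -> set:
        return {g for g, ts in self.gene_terms.items() if term in ts}


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _read_rows(path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def read_design(path) -> ArrayDesign:
    """Parse a two-section design file into a validated :class:`ArrayDesign`."""
    rows = _read_rows(path)
    section = None
    channel_rows: list[dict] = []
    spot_rows: list[dict] = []
    for lineno, fields in rows:
        first = fields[0].strip().lower()
        if first in ("[channels]", "[spots]"):
            section = first.strip("[]")
            continue
        if section is None:
            raise FormatError(f"{path}:{lineno}: content before any section header")
        if section == "channels":
            if [f.strip().lower() for f in fields[:4]] == CHANNEL_COLUMNS:
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 channel columns")
            array, dye, sample, group = (f.strip() for f in fields[:4])
            dye = _canonical_dye(dye, f" at {path}:{lineno}")
            channel_rows.append(
                {"array": array, "dye": dye, "sample": sample, "group": group}
            )
        else:
            if [f.strip().lower() for f in fields[:4]] == SPOT_COLUMNS:
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 spot columns")
            spot, transcript, dup, block = (f.strip() for f in fields[:4])
            try:
                dup_i = int(dup)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: duplicate_index {dup!r} is not an integer"
                ) from exc
            spot_rows.append(
                {"spot": spot, "transcript": transcript,
                 "duplicate_index": dup_i, "block": block}
            )
    if not channel_rows:
        raise FormatError(f"{path}: no [channels] section")
    ch = pd.DataFrame(channel_rows)
    dup = ch.duplicated(subset=["array", "dye"])
    if dup.any():
        row = ch[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate (array, dye) channel ({row['array']}, {row['dye']})"
        )
    design = ArrayDesign(ch, pd.DataFrame(spot_rows, columns=SPOT_COLUMNS))
    logger.info(
        "read design: %d arrays, %d channels, %d spots, loop_connected=%s",
        design.n_arrays, design.n_channels, len(design.spots),
        design.loop_connected,
    )
    return design


def write_design(design: ArrayDesign, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("[channels]\n")
        fh.write("\t".join(CHANNEL_COLUMNS) + "\n")
        for _, row in design.channels.iterrows():
            fh.write("\t".join(str(row[c]) for c in CHANNEL_COLUMNS) + "\n")
        fh.write("[spots]\n")
        fh.write("\t".join(SPOT_COLUMNS) + "\n")
        for _, row in design.spots.iterrows():
            fh.write("\t".join(str(row[c]) for c in SPOT_COLUMNS) + "\n")


def read_intensities(path, design: ArrayDesign) -> IntensityMatrix:
    """Read a long intensity table and validate its keys against *design*."""
    return IntensityMatrix(_read_long(path, design, allow_negative=False))


def read_expression(path, design: ArrayDesign) -> ExpressionMatrix:
    """Read a log2-scale (or residual) table; negative values are legal."""
    return ExpressionMatrix(_read_long(path, design, allow_negative=True))


def _read_long(path, design: ArrayDesign, allow_negative: bool) -> pd.DataFrame:
    rows = _read_rows(path)
    recs = []
    valid_spots = set(design.spots["spot"])
    valid_channels = set(zip(design.channels["array"], design.channels["dye"]))
    for lineno, fields in rows:
        if [f.strip().lower() for f in fields[:4]] == INTENSITY_COLUMNS:
            continue
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        spot, array, dye, raw = (f.strip() for f in fields[:4])
        dye = _canonical_dye(dye, f" at {path}:{lineno}")
        if spot not in valid_spots:
            raise FormatError(f"{path}:{lineno}: spot {spot!r} not in design")
        if (array, dye) not in valid_channels:
            raise FormatError(
                f"{path}:{lineno}: channel ({array}, {dye}) not in design"
            )
        if raw in ("", "NA", "na", "NaN", "nan"):
            value = np.nan
        else:
            try:
                value = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: intensity {raw!r} is not numeric"
                ) from exc
            if value < 0 and not allow_negative:
                raise FormatError(f"{path}:{lineno}: negative intensity {raw}")
        recs.append({"spot": spot, "array": array, "dye": dye, "intensity": value})
    return pd.DataFrame(recs, columns=INTENSITY_COLUMNS)


def write_intensities(matrix: IntensityMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(INTENSITY_COLUMNS) + "\n")
        for _, row in matrix.values.iterrows():
            val = "NA" if pd.isna(row["intensity"]) else repr(float(row["intensity"]))
            fh.write(f"{row['spot']}\t{row['array']}\t{row['dye']}\t{val}\n")


def read_annotation(gene2term_path, slim_path, universe) -> AnnotationMap:
    """Read gene->term and term->ancestor TSVs.

    Genes annotated but absent from *universe* are dropped with a logged
    count (``n_dropped``); duplicate rows collapse to one mapping.
    """
    universe = set(universe)
    gene_terms: dict = {}
    n_dropped = 0
    for _, fields in _read_rows(gene2term_path):
        if len(fields) < 2:
            raise FormatError(f"{gene2term_path}: expected 2 columns")
        gene, term = fields[0].strip(), fields[1].strip()
        if gene not in universe:
            n_dropped += 1
            continue
        gene_terms.setdefault(gene, set()).add(term)
    if n_dropped:
        logger.warning("dropped %d annotation rows for genes outside the universe",
                       n_dropped)
    slim: dict = {}
    if slim_path is not None:
        for _, fields in _read_rows(slim_path):
            if len(fields) < 2:
                raise FormatError(f"{slim_path}: expected 2 columns")
            term, anc = fields[0].strip(), fields[1].strip()
            slim.setdefault(term, set()).add(anc)
    return AnnotationMap(gene_terms=gene_terms, slim=slim, universe=universe,
                         n_dropped=n_dropped)


def write_annotation(annotation: AnnotationMap, gene2term_path, slim_path=None) -> None:
    with open(gene2term_path, "w", encoding="utf-8") as fh:
        for gene in sorted(annotation.gene_terms):
            for term in sorted(annotation.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    if slim_path is not None:
        with open(slim_path, "w", encoding="utf-8") as fh:
            for term in sorted(annotation.slim):
                for anc in sorted(annotation.slim[term]):
                    fh.write(f"{term}\t{anc}\n")
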