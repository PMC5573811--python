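"""Degenerate protein motif compilation and scanning.

Terpene synthases carry a small kit of short conserved motifs: the N-terminal
tandem-arginine motif (RRX8W, required for monoterpene cyclization), the RDR
motif, the aspartate-rich DDXXD and the NSE/DTE triad — the last two jointly
coordinate the trio of Mg2+ ions that ionizes the prenyl diphosphate
substrate. Class II (protonation-initiated) cyclases carry DXDD instead of
DDXXD.

Pattern notation (field convention): fixed residues as plain letters,
slash-separated alternatives in parentheses, X as a one-residue wildcard and
X followed by an integer as a fixed-length wildcard run. "RRX8W" is R, R,
eight wildcards, W (length 11).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genome_io import AMINO_ACIDS, ProteinRecord

FULL_ALPHABET = frozenset(AMINO_ACIDS)

#: canonical N→C order of the generic required motifs
REQUIRED_MOTIF_ORDER = ("RRX8W", "RDR", "DDXXD", "NSE/DTE")


class MotifSyntaxError(ValueError):
    """Malformed pattern notation; carries the 1-based column of the error."""

    def __init__(self, message: str, column: int):
        super().__init__(f"column {column}: {message}")
        self.column = column


@dataclass(frozen=True)
class MotifPattern:
    """Compiled degenerate pattern: one residue set per position.

    A wildcard position is the full 20-letter set. X in a *protein* never
    matches any position (conservative: unknown residues prove nothing).
    """

    name: str
    elements: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.elements)

    def matches_at(self, residues: str, start: int) -> bool:
        """0-based start; True iff the window matches every position."""
        if start < 0 or start + len(self.elements) > len(residues):
            return False
        return all(
            residues[start + i] in allowed for i, allowed in enumerate(self.elements)
        )


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif: str
    start: int  # 1-based residue index
    matched: str


def compile_pattern(spec: str, name: str | None = None) -> MotifPattern:
    """Compile field notation (e.g. ``"R(D/N)R"``, ``"RRX8W"``) to a pattern."""
    elements: list[frozenset] = []
    i = 0
    n = len(spec)
    while i < n:
        c = spec[i]
        col = i + 1
        if c == "(":
            close = spec.find(")", i)
            if close == -1:
                raise MotifSyntaxError("unclosed '('", col)
            body = spec[i + 1 : close]
            alts = body.split("/")
            if not body or any(len(a) != 1 or a not in AMINO_ACIDS for a in alts):
                raise MotifSyntaxError(f"bad alternation {body!r}", col + 1)
            elements.append(frozenset(alts))
            i = close + 1
        elif c == "X":
            j = i + 1
            while j < n and spec[j].isdigit():
                j += 1
            repeat = int(spec[i + 1 : j]) if j > i + 1 else 1
            if repeat < 1:
                raise MotifSyntaxError("wildcard repeat must be >= 1", col + 1)
            elements.extend([FULL_ALPHABET] * repeat)
            i = j
        elif c in AMINO_ACIDS:
            elements.append(frozenset(c))
            i += 1
        else:
            raise MotifSyntaxError(f"unexpected character {c!r}", col)
    if not elements:
        raise MotifSyntaxError("empty pattern", 1)
    return MotifPattern(name=name or spec, elements=tuple(elements))


def scan(protein: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) hits, ascending by position (1-based)."""
    residues = protein.residues
    hits = []
    for start in range(len(residues) - len(pattern) + 1):
        if pattern.matches_at(residues, start):
            hits.append(
                MotifHit(
                    protein_id=protein.protein_id,
                    motif=pattern.name,
                    start=start + 1,
                    matched=residues[start : start + len(pattern)],
                )
            )
    return hits


@dataclass
class MotifCompleteness:
    protein_id: str
    presence: dict[str, bool]
    first_positions: dict[str, int | None]
    complete: bool
    in_canonical_order: bool


def motif_completeness(
    protein: ProteinRecord,
    required: Mapping[str, MotifPattern] | None = None,
) -> MotifCompleteness:
    """Presence of each required motif; complete = all present.

    The canonical N→C order (arginine motif, RDR, DDXXD, NSE/DTE) is checked
    on first occurrences and reported separately — it is informative, not a
    condition for completeness.
    """
    if required is None:
        required = default_required_patterns()
    presence: dict[str, bool] = {}
    first: dict[str, int | None] = {}
    for name, pattern in required.items():
        hits = scan(protein, pattern)
        presence[name] = bool(hits)
        first[name] = hits[0].start if hits else None
    positions = [first[name] for name in required if first[name] is not None]
    ordered = all(a < b for a, b in zip(positions, positions[1:]))
    return MotifCompleteness(
        protein_id=protein.protein_id,
        presence=presence,
        first_positions=first,
        complete=all(presence.values()),
        in_canonical_order=ordered and all(presence.values()),
    )


# ---------------------------------------------------------------------------
# Packaged motif library
# ---------------------------------------------------------------------------

def load_motif_library(path: str | Path | None = None) -> pd.DataFrame:
    """Load the motif table (columns: name, subfamily, pattern).

    Defaults to the packaged library covering the generic TPS kit and the
    TPS-a / TPS-b / TPS-g / TPS-c subfamily consensuses.
    """
    if path is None:
        with resources.files("tpsfam.data").joinpath("motif_library.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def compile_library(
    library: pd.DataFrame | None = None, subfamily: str = "generic"
) -> dict[str, MotifPattern]:
    """Compile one subfamily's motif set from the library table."""
    if library is None:
        library = load_motif_library()
    sub = library[library["subfamily"] == subfamily]
    return {
        row["name"]: compile_pattern(row["pattern"], name=row["name"])
        for _, row in sub.iterrows()
    }


def default_required_patterns() -> dict[str, MotifPattern]:
    """The four generic motifs required for mono/sesquiterpene synthase activity."""
    lib = compile_library(subfamily="generic")
    return {name: lib[name] for name in REQUIRED_MOTIF_ORDER}


def hits_table(proteins: Iterable[ProteinRecord], patterns: Mapping[str, MotifPattern]) -> pd.DataFrame:
    rows = []
    for protein in proteins:
        for pattern in patterns.values():
            for hit in scan(protein, pattern):
                rows.append(
                    {
                        "protein_id": hit.protein_id,
                        "motif": hit.motif,
                        "start": hit.start,
                        "matched": hit.matched,
                    }
                )
    return pd.DataFrame(rows, columns=["protein_id", "motif", "start", "matched"])
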