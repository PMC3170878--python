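"""Variant-label parsing for GLA missense mutations.

Handles the notation used for the assay panel: protein changes like
``p.R301Q`` and cDNA changes like ``c.902G>A``, plus slash-joined double
substitutions (``p.D55V/Q57L`` / ``c.164A>T/170C>T``).  Nucleotide numbering
has +1 at the A of the ATG initiation codon and the initiation codon is
codon 1, so a cDNA position ``nt`` falls in codon ``ceil(nt/3)``.

Only the substitution forms above are supported; this is not a general HGVS
parser.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
BASES = set("ACGT")

_PROT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_CDNA_RE = re.compile(r"^(\d+)([ACGT])>([ACGT])$")


class VariantParseError(ValueError):
    """Raised for malformed protein or cDNA substitution syntax."""


@dataclass(frozen=True)
class ProteinSub:
    ref_residue: str
    position: int
    alt_residue: str

    def __str__(self) -> str:
        return f"{self.ref_residue}{self.position}{self.alt_residue}"


@dataclass(frozen=True)
class CdnaSub:
    nt_position: int
    ref_base: str
    alt_base: str

    def __str__(self) -> str:
        return f"{self.nt_position}{self.ref_base}>{self.alt_base}"

    @property
    def codon(self) -> int:
        return math.ceil(self.nt_position / 3)


@dataclass(frozen=True)
class VariantLabel:
    """A parsed protein/cDNA variant pair.

    ``multi`` is True for double mutants; ``consistent`` records whether
    every single substitution maps the cDNA position onto the stated codon
    (a warning-level check: fixture rows load regardless).
    """

    protein_change: str
    cdna_change: str
    protein_subs: tuple[ProteinSub, ...] = field(default=())
    cdna_subs: tuple[CdnaSub, ...] = field(default=())
    multi: bool = False
    consistent: bool = True

    def __str__(self) -> str:  # round-trips the input text
        return f"{self.protein_change} ({self.cdna_change})"


def _parse_protein_part(token: str) -> ProteinSub:
    m = _PROT_RE.match(token)
    if not m:
        raise VariantParseError(f"malformed protein substitution: {token!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
        raise VariantParseError(f"invalid amino acid code in {token!r}")
    if pos < 1:
        raise VariantParseError(f"non-positive residue position in {token!r}")
    return ProteinSub(ref, pos, alt)


def _parse_cdna_part(token: str) -> CdnaSub:
    m = _CDNA_RE.match(token)
    if not m:
        raise VariantParseError(f"malformed cDNA substitution: {token!r}")
    pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    if pos < 1:
        raise VariantParseError(f"non-positive nucleotide position in {token!r}")
    return CdnaSub(pos, ref, alt)


def parse_variant(protein_text: str, cdna_text: str) -> VariantLabel:
    """Parse a protein/cDNA label pair such as ``("p.R301Q", "c.902G>A")``.

    Double mutants are split on ``/`` (the ``p.``/``c.`` prefix appears only
    on the first part, as printed).  For each single substitution the codon
    implied by the cDNA position, ``ceil(nt/3)``, is checked against the
    protein position; mismatches set ``consistent=False`` without raising.
    """
    if not protein_text or not cdna_text:
        raise VariantParseError("empty variant label")
    if not protein_text.startswith("p."):
        raise VariantParseError(f"protein label must start with 'p.': {protein_text!r}")
    if not cdna_text.startswith("c."):
        raise VariantParseError(f"cDNA label must start with 'c.': {cdna_text!r}")

    prot_tokens = protein_text[2:].split("/")
    cdna_tokens = cdna_text[2:].split("/")
    if len(prot_tokens) != len(cdna_tokens):
        raise VariantParseError(
            f"protein and cDNA labels list different numbers of substitutions: "
            f"{protein_text!r} vs {cdna_text!r}"
        )

    prot_subs = tuple(_parse_protein_part(t) for t in prot_tokens)
    cdna_subs = tuple(_parse_cdna_part(t) for t in cdna_tokens)
    consistent = all(c.codon == p.position for p, c in zip(prot_subs, cdna_subs))
    return VariantLabel(
        protein_change=protein_text,
        cdna_change=cdna_text,
        protein_subs=prot_subs,
        cdna_subs=cdna_subs,
        multi=len(prot_subs) > 1,
        consistent=consistent,
    )


def format_variant(label: VariantLabel) -> tuple[str, str]:
    """Re-render a parsed label; inverse of :func:`parse_variant`."""
    prot = "p." + "/".join(str(s) for s in label.protein_subs)
    cdna = "c." + "/".join(str(s) for s in label.cdna_subs)
    return prot, cdna
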