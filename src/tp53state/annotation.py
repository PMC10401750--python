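"""TP53 variant annotation: HGVS-p parsing, hotspot membership, MDS risk.

The six canonical DNA-binding-domain hotspots (R175H, Y220C, M237I, R248Q,
R273H, R282W) account for the majority of missense TP53 mutations in myeloid
neoplasia; a variant within ±5 residues of a hotspot is treated as canonical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

logger = logging.getLogger(__name__)

TP53_PROTEIN_LENGTH = 393

#: residue positions of the canonical missense hotspots
CANONICAL_HOTSPOTS = frozenset({175, 220, 237, 248, 273, 282})


@dataclass(frozen=True)
class HotspotCatalog:
    canonical_positions: frozenset[int] = CANONICAL_HOTSPOTS
    window: int = 5

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        bad = [p for p in self.canonical_positions
               if not 1 <= p <= TP53_PROTEIN_LENGTH]
        if bad:
            raise ValueError(f"positions outside TP53 protein (1-393): {bad}")

    @classmethod
    def from_yaml(cls, path) -> "HotspotCatalog":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(
            canonical_positions=frozenset(cfg.get(
                "canonical_positions", sorted(CANONICAL_HOTSPOTS))),
            window=int(cfg.get("window", 5)),
        )


_HGVS_RE = re.compile(
    r"^p\.\(?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z*])"
    r"(?P<pos>\d+)"
    r"(?P<rest>.*?)\)?$"
)

_AA3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}


def parse_protein_change(hgvs_p: str) -> tuple[Optional[int], str]:
    """Parse an HGVS-p string like ``p.R175H`` into (position, consequence).

    Substitution to a different residue -> missense; a stop ("*"/"Ter") or
    frameshift ("fs") -> truncating; anything mentioning a splice effect ->
    splice.  An empty string yields (None, "other") silently; an unparseable
    non-empty string does the same with a warning.
    """
    if not hgvs_p:
        return None, "other"
    s = hgvs_p.strip()
    if "splice" in s.lower():
        return None, "splice"
    m = _HGVS_RE.match(s)
    if not m:
        logger.warning("unparseable protein change %r", hgvs_p)
        return None, "other"
    pos = int(m.group("pos"))
    ref = _AA3.get(m.group("ref"), m.group("ref"))
    rest = m.group("rest")
    if "fs" in rest:
        return pos, "truncating"
    alt = _AA3.get(rest, rest)
    if alt in ("*", "Ter"):
        return pos, "truncating"
    if re.fullmatch(r"[A-Z]", alt) and alt != ref:
        return pos, "missense"
    if re.fullmatch(r"[A-Z]", alt) and alt == ref:  # synonymous
        return pos, "other"
    logger.warning("unrecognized protein-change suffix in %r", hgvs_p)
    return pos, "other"


def is_canonical(aa_position: Optional[int],
                 catalog: HotspotCatalog = HotspotCatalog()) -> bool:
    """True iff the residue lies within ``catalog.window`` of a canonical
    hotspot (inclusive boundary).  Intended for missense variants; the caller
    decides applicability.  A missing position is never canonical."""
    if aa_position is None:
        logger.warning("is_canonical called with missing position")
        return False
    if aa_position < 1:
        raise ValueError("aa_position must be >= 1")
    return any(abs(aa_position - c) <= catalog.window
               for c in catalog.canonical_positions)


def classify_mds_risk(blast_pct: Optional[float]) -> Optional[str]:
    """High-risk vs low-risk MDS from the marrow blast percentage:
    HR at >= 5% blasts.  ``blast_pct`` is on the percent scale."""
    if blast_pct is None:
        return None
    if not 0 <= blast_pct <= 100:
        raise ValueError(f"blast_pct must be in [0, 100], got {blast_pct}")
    return "HR" if blast_pct >= 5 else "LR"
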