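"""In-silico PCR screening of 16S rRNA gene sequences with degenerate
(IUPAC) primers: exhaustive ungapped best-site matching on both strands,
amplifiability classification (mismatch / 3'-mismatch / oversized-
amplicon-i.e.-intron criteria), and per-lineage blind-spot flagging.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp

logger = logging.getLogger(__name__)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = np.zeros(256, dtype=np.uint8)
for _c, _bases in IUPAC_SETS.items():
    _CODE_BITS[ord(_c)] = sum(_BITS[b] for b in _bases)
# plain sequence bases (N in a *sequence* is unknown: matches nothing)
for _c in "ACGT":
    _CODE_BITS[ord(_c)] = _BITS[_c]
_SEQ_BITS = _CODE_BITS.copy()
_SEQ_BITS[ord("N")] = 0


@dataclass
class PrimerSet:
    fw: str
    rv: str
    expected_amplicon: tuple[int, int] = (300, 600)

    def __post_init__(self) -> None:
        for name, p in (("fw", self.fw), ("rv", self.rv)):
            _validate_iupac(p)
            if not (15 <= len(p) <= 30):
                raise ValueError(f"{name} primer length must be 15-30, got {len(p)}")


@dataclass
class PrimerSite:
    pos: int  # window start, forward-strand coordinates
    strand: str
    mismatches: int
    three_prime_mismatches: int


@dataclass
class AmplifiabilityResult:
    seq_id: str
    fw_site: Optional[PrimerSite]
    rv_site: Optional[PrimerSite]
    amplicon_len: Optional[int]
    verdict: str  # pass | fail_mismatch | fail_intron | fail_no_site
    reasons: list = field(default_factory=list)


def _validate_iupac(primer: str) -> None:
    for i, c in enumerate(primer):
        if c.upper() not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {c!r} at position {i} of primer {primer!r}")


def _scan(seq_bits: np.ndarray, primer_bits: np.ndarray) -> np.ndarray:
    m = primer_bits.size
    n = seq_bits.size - m + 1
    out = np.zeros(n, dtype=np.int64)
    for i in range(m):
        out += (seq_bits[i : i + n] & primer_bits[i]) == 0
    return out


def primer_match(seq: str, primer: str) -> PrimerSite:
    """Best ungapped primer site over both strands.

    IUPAC degeneracy codes in the primer match their base sets; N in the
    subject sequence matches nothing.  Best = fewest total mismatches,
    ties broken by smallest forward-strand position (plus strand first).
    Mismatches within the 4 3'-terminal primer bases are counted
    separately.
    """
    _validate_iupac(primer)
    seq = seq.upper()
    primer = primer.upper()
    if len(seq) < len(primer):
        raise ValueError("sequence shorter than primer")
    m = len(primer)
    pb = _CODE_BITS[np.frombuffer(primer.encode(), dtype=np.uint8)]
    best: Optional[PrimerSite] = None
    for strand, subject in (("+", seq), ("-", revcomp(seq))):
        sb = _SEQ_BITS[np.frombuffer(subject.encode(), dtype=np.uint8)]
        mm = _scan(sb, pb)
        # per-strand candidates in scan coordinates; convert minus-strand
        # starts back to forward coordinates for the tie rule
        for p in np.flatnonzero(mm == mm.min()):
            fwd_pos = int(p) if strand == "+" else len(seq) - (int(p) + m)
            tp = int(
                sum(
                    (sb[p + k] & pb[k]) == 0
                    for k in range(m - 4, m)
                )
            )
            site = PrimerSite(pos=fwd_pos, strand=strand, mismatches=int(mm[p]), three_prime_mismatches=tp)
            if best is None or (site.mismatches, site.pos) < (best.mismatches, best.pos):
                best = site
    return best


def classify(
    seq_id: str,
    seq: str,
    primers: PrimerSet,
    max_total_mm: int = 1,
    max_3prime_mm: int = 0,
    intron_excess: int = 150,
    fail_floor: int = 5,
) -> AmplifiabilityResult:
    """Amplifiability verdict for one 16S sequence.

    fail_no_site: either primer's best site exceeds the mismatch floor
    (or the implied amplicon is shorter than expected).  fail_mismatch:
    total mismatches above max_total_mm or any 3'-terminal mismatch above
    max_3prime_mm on either primer.  fail_intron: inter-primer distance
    exceeds the expected amplicon maximum by more than intron_excess
    (large insertions hamper amplification).  Reasons accumulate; the
    verdict is the first failing rule in the order above.
    """
    fw = primer_match(seq, primers.fw)
    rv = primer_match(seq, primers.rv)
    reasons = []
    if fw.mismatches > fail_floor:
        reasons.append("fw_no_site")
    if rv.mismatches > fail_floor:
        reasons.append("rv_no_site")
    for name, site in (("fw", fw), ("rv", rv)):
        if site.mismatches > max_total_mm:
            reasons.append(f"{name}_mismatch({site.mismatches})")
        elif site.three_prime_mismatches > max_3prime_mm:
            reasons.append(f"{name}_3prime_mismatch({site.three_prime_mismatches})")
    # amplicon span between the outermost primer coordinates
    left, right = (fw, rv) if fw.pos <= rv.pos else (rv, fw)
    amplicon = (right.pos + (len(primers.rv) if right is rv else len(primers.fw))) - left.pos
    lo, hi = primers.expected_amplicon
    if amplicon > hi + intron_excess:
        reasons.append(f"intron({amplicon})")
    elif amplicon < lo:
        reasons.append(f"amplicon_too_short({amplicon})")
    if any(r.endswith("no_site") or r.startswith("amplicon_too_short") for r in reasons):
        verdict = "fail_no_site"
    elif any("mismatch" in r for r in reasons):
        verdict = "fail_mismatch"
    elif any(r.startswith("intron") for r in reasons):
        verdict = "fail_intron"
    else:
        verdict = "pass"
    return AmplifiabilityResult(
        seq_id=seq_id,
        fw_site=fw,
        rv_site=rv,
        amplicon_len=int(amplicon),
        verdict=verdict,
        reasons=reasons,
    )


def results_to_frame(results: list[AmplifiabilityResult], lineages: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "lineage": lineages.get(r.seq_id, ""),
                "verdict": r.verdict,
                "fw_mm": r.fw_site.mismatches,
                "fw_3prime_mm": r.fw_site.three_prime_mismatches,
                "rv_mm": r.rv_site.mismatches,
                "amplicon_len": r.amplicon_len,
                "reasons": ";".join(r.reasons),
            }
            for r in results
        ]
    )


def lineage_blindspot(results: pd.DataFrame, fail_frac_threshold: float = 0.8) -> pd.DataFrame:
    """Per-lineage amplification blind spots: a lineage is flagged iff
    strictly more than fail_frac_threshold of its genomes fail."""
    rows = []
    for lineage, grp in results.groupby("lineage", sort=True):
        frac = float((grp["verdict"] != "pass").mean())
        rows.append(
            {
                "lineage": lineage,
                "n": len(grp),
                "fail_fraction": frac,
                "flagged": frac > fail_frac_threshold,
            }
        )
    return pd.DataFrame(rows)
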