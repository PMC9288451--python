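"""Mouse–human miRNA conservation scoring.

Seed regions (mature positions 2–7) and full mature sequences of same-name
mouse/human miRNA pairs are globally aligned (Needleman–Wunsch) under a
match=1 / mismatch=0 substitution scheme with a linear gap penalty.  A pair is
"conserved" exactly when its seed score is 6 (perfect 6/6 seed identity: with
match 1, mismatch 0 and a negative gap penalty, gaps are never optimal for
equal-length seeds, so the score counts matching positions).  A secondary
"mature high similarity" flag marks pairs whose full mature alignment score
passes a threshold of 20 matched bases (inclusive by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import FormatsError, InvalidAlphabetError, MiRNARecord, RNA_ALPHABET

MATCH_SCORE = 1.0
MISMATCH_SCORE = 0.0
GAP_SCORE = -2.0
MATURE_THRESHOLD = 20.0
SEED_LEN = 6


class PairingError(FormatsError):
    """Records cannot form a cross-species ortholog pair."""


def extract_seed(mature_seq: str) -> str:
    """Seed region: characters at 1-based positions 2..7 of the mature sequence."""
    seq = mature_seq.upper().replace("T", "U")
    if len(seq) < 7:
        raise FormatsError(f"mature sequence too short for a seed: {seq!r}")
    if set(seq) - RNA_ALPHABET:
        raise InvalidAlphabetError(f"non-RNA symbols in {seq!r}")
    return seq[1:7]


def nw_global_score(a: str, b: str, match: float = MATCH_SCORE,
                    mismatch: float = MISMATCH_SCORE,
                    gap: float = GAP_SCORE) -> float:
    """Optimal Needleman–Wunsch global alignment score, linear gap penalty.

    With match=1, mismatch=0 and any negative gap penalty, equal-length inputs
    have a gapless optimum and the score equals the number of matching
    positions — which is what makes the seed-score-6 conservation rule a
    seed-identity rule.
    """
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    if not a or not b:
        raise FormatsError("alignment inputs must be non-empty")
    for seq in (a, b):
        if set(seq) - RNA_ALPHABET:
            raise InvalidAlphabetError(f"non-RNA symbols in {seq!r}")
    n, m = len(a), len(b)
    prev = np.arange(m + 1, dtype=float) * gap
    cur = np.empty(m + 1, dtype=float)
    bvec = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    for i in range(1, n + 1):
        cur[0] = i * gap
        sub = np.where(bvec == ord(a[i - 1]), match, mismatch)
        diag = prev[:-1] + sub
        for j in range(1, m + 1):
            cur[j] = max(diag[j - 1], prev[j] + gap, cur[j - 1] + gap)
        prev, cur = cur, prev
    return float(prev[m])


@dataclass(frozen=True)
class ConservationCall:
    """Conservation classification of one mouse–human miRNA pair."""

    mouse_name: str
    human_name: str
    seed_score: float
    mature_score: float
    category: str                 # conserved | non_conserved
    mature_high_similarity: bool
    mouse_mature_seq: str = ""


def classify_conservation(mouse: MiRNARecord, human: MiRNARecord,
                          mature_threshold: float = MATURE_THRESHOLD,
                          inclusive: bool = True,
                          gap: float = GAP_SCORE) -> ConservationCall:
    """Score and categorise one same-name mouse/human pair.

    ``inclusive`` selects mature_score ≥ threshold for the high-similarity
    flag (default); strict mode requires a score strictly above it.
    """
    if mouse.species == human.species:
        raise PairingError("conservation pairs must span two species")
    if mouse.species != "mouse" or human.species != "human":
        raise PairingError("expected (mouse, human) record order")
    if mouse.base_name != human.base_name:
        raise PairingError(
            f"names {mouse.name!r} and {human.name!r} do not match after "
            "stripping species prefixes")
    seed_score = nw_global_score(mouse.seed, human.seed, gap=gap)
    mature_score = nw_global_score(mouse.mature_seq, human.mature_seq, gap=gap)
    category = "conserved" if seed_score == SEED_LEN else "non_conserved"
    if inclusive:
        high = mature_score >= mature_threshold
    else:
        high = mature_score > mature_threshold
    return ConservationCall(
        mouse_name=mouse.name, human_name=human.name,
        seed_score=seed_score, mature_score=mature_score,
        category=category, mature_high_similarity=bool(high),
        mouse_mature_seq=mouse.mature_seq,
    )


def classify_all(mouse_records, human_records,
                 mature_threshold: float = MATURE_THRESHOLD,
                 inclusive: bool = True, gap: float = GAP_SCORE) -> pd.DataFrame:
    """Pair records by base name across species and classify every pair.

    Mouse miRNAs without a same-name human partner appear with category
    ``unpaired`` (treated as non-conserved by downstream exclusion filters).
    """
    humans = {}
    for rec in human_records:
        if rec.base_name in humans:
            raise FormatsError(f"multiple human records named {rec.base_name!r}")
        humans[rec.base_name] = rec
    rows = []
    for mouse in mouse_records:
        partner = humans.get(mouse.base_name)
        if partner is None:
            rows.append({
                "mouse_name": mouse.name, "human_name": None,
                "seed_score": np.nan, "mature_score": np.nan,
                "category": "unpaired", "mature_high_similarity": False,
                "mouse_mature_seq": mouse.mature_seq,
            })
            continue
        call = classify_conservation(mouse, partner,
                                     mature_threshold=mature_threshold,
                                     inclusive=inclusive, gap=gap)
        rows.append(vars(call) if not hasattr(call, "__dataclass_fields__")
                    else {f: getattr(call, f) for f in call.__dataclass_fields__})
    return pd.DataFrame(rows)
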