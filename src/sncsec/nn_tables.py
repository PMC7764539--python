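"""Nearest-neighbor free-energy parameters for RNA duplex stacks.

Watson-Crick stack free energies (dG at 37 C, kcal/mol) are the
Xia-1998 values; G:U wobble stacks are the Turner-set values at 0.1
kcal precision.  A stack is written 5'-x1 x2-3' paired with
3'-y1 y2-5' and keyed ``(x1+y1, x2+y2)``; reading the same physical
stack from the other strand gives the key ``(y2+x2, y1+x1)``, so
lookups canonicalize over the two representations.
"""

from __future__ import annotations

#: Duplex initiation penalty, kcal/mol.
INITIATION_DG = 4.09

#: Fixed penalty per internal helix interruption (mismatch/gap run
#: between paired stretches), kcal/mol.
LOOP_PENALTY_DG = 3.0

_WC_STACKS = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
}

_GU_STACKS = {
    ("CG", "GU"): -1.40,
    ("CG", "UG"): -2.10,
    ("GC", "GU"): -1.50,
    ("GC", "UG"): -2.50,
    ("AU", "GU"): -0.60,
    ("AU", "UG"): -1.40,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.30,
    ("GU", "CG"): -2.50,
    ("GU", "GC"): -2.10,
    ("GU", "AU"): -1.30,
    ("GU", "UA"): -1.40,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): 1.30,
    ("UG", "GU"): 0.30,
    ("UG", "UG"): -0.50,
}

_PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}


def _rev(pair: str) -> str:
    return pair[::-1]


def stack_dg(p1: str, p2: str) -> float:
    """Free energy of the stack of base pair ``p1`` on ``p2``.

    ``p1``/``p2`` are two-letter pair strings (5' strand base then 3'
    strand base), e.g. ``stack_dg("GC", "GC")`` is the 5'GG3'/3'CC5'
    stack (-3.26).  Raises KeyError for non-pairable letters.
    """
    if p1 not in _PAIRS or p2 not in _PAIRS:
        raise KeyError(f"not a canonical RNA pair: {p1}/{p2}")
    for key in ((p1, p2), (_rev(p2), _rev(p1))):
        if key in _WC_STACKS:
            return _WC_STACKS[key]
        if key in _GU_STACKS:
            return _GU_STACKS[key]
    raise KeyError(f"no stack parameter for {p1}/{p2}")
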