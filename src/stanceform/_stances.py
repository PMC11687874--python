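"""Canonical stance labels and orderings shared across modules."""

PRO = "pro"
NEUTRAL = "neutral"
ANTI = "anti"

#: Canonical order; also the default tie-break priority (highest first),
#: chosen to follow the classifier's per-class precision ordering.
STANCES = (PRO, NEUTRAL, ANTI)

STANCE_INDEX = {s: i for i, s in enumerate(STANCES)}


def check_stance(value: str) -> str:
    if value not in STANCE_INDEX:
        raise ValueError(f"unknown stance label: {value!r} (expected one of {STANCES})")
    return value
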