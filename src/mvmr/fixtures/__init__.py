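"""Shipped plain-text variant lists for the three-lipid CAD analysis.

These are the published exclusion lists: 23 variants with known pleiotropic
associations with blood pressure or body mass index, and the variants
removed by heterogeneity pruning at the 98th, 95th and 90th percentiles
(each percentile list is cumulative: the 95th includes the 98th's variants,
and so on).
"""

from __future__ import annotations

from importlib import resources

__all__ = ["available_lists", "load_exclusion_list"]

_FILES = {
    "pleiotropy_bp_bmi": "pleiotropy_bp_bmi.txt",
    "pruned_98th": "pruned_98th.txt",
    "pruned_95th_additional": "pruned_95th_additional.txt",
    "pruned_90th_additional": "pruned_90th_additional.txt",
}


def available_lists() -> list[str]:
    return sorted(_FILES)


def load_exclusion_list(name: str) -> list[str]:
    """Variant ids from a shipped list (or from ``pruned_95th``/``pruned_90th``
    for the cumulative pruning sets)."""
    if name == "pruned_95th":
        return load_exclusion_list("pruned_98th") + load_exclusion_list(
            "pruned_95th_additional"
        )
    if name == "pruned_90th":
        return load_exclusion_list("pruned_95th") + load_exclusion_list(
            "pruned_90th_additional"
        )
    if name not in _FILES:
        raise KeyError(f"unknown list {name!r}; available: {available_lists()}")
    text = resources.files(__package__).joinpath(_FILES[name]).read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
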