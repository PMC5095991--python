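"""Scenario-name grammar for prediction models and QTL-component recipes.

A scenario name encodes the prediction model and how its QTL component was
built::

    <WB|MB|MT>-50K[+<WB|MB>QTL<t>[-<n>/<w>]]

``WB`` is within-breed single-trait prediction, ``MB`` pools breeds with a
fixed breed effect, and ``MT`` treats the same trait in different breeds as
correlated traits.  The optional suffix names the QTL component: the GWAS it
came from (within-breed or multi-breed), the p-value threshold exponent
``t`` (variants with p below ``10**-t``), and optionally a per-interval cap
of ``n`` variants per window of ``w`` Mb.  Examples: ``WB-50K``,
``MB-50K+MBQTL14-10/2``, ``MT-50K+MBQTL20-25/10``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["ScenarioSpec", "parse_scenario"]

_GRAMMAR = re.compile(
    r"^(?P<model>WB|MB|MT)-50K"
    r"(?:\+(?P<source>WB|MB)QTL(?P<t>\d+)"
    r"(?:-(?P<n>\d+)/(?P<w>\d+(?:\.\d+)?))?)?$"
)

_GRAMMAR_HELP = "<WB|MB|MT>-50K[+<WB|MB>QTL<t>[-<n>/<w>]] (e.g. WB-50K, MB-50K+MBQTL14-10/2)"


@dataclass(frozen=True)
class ScenarioSpec:
    """A parsed scenario: prediction model plus QTL-component recipe.

    ``model`` is WB, MB or MT; ``qtl_source`` (WB or MB) names the GWAS the
    QTL component came from, or ``None`` for array-only scenarios; ``t`` is
    the threshold exponent; ``n``/``w`` cap the component at ``n`` variants
    per ``w``-Mb peak interval (both present or both absent).
    """

    model: str
    qtl_source: str | None = None
    t: int | None = None
    n: int | None = None
    w: float | None = None

    def __post_init__(self) -> None:
        if self.model not in {"WB", "MB", "MT"}:
            raise ValueError(f"unknown model family {self.model!r}")
        if self.qtl_source is not None:
            if self.qtl_source not in {"WB", "MB"}:
                raise ValueError(f"unknown QTL source {self.qtl_source!r}")
            if self.t is None or self.t <= 0:
                raise ValueError("a QTL component requires a positive threshold exponent t")
        elif self.t is not None or self.n is not None or self.w is not None:
            raise ValueError("t/n/w given without a QTL source")
        if (self.n is None) != (self.w is None):
            raise ValueError("n and w must be given together")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")
        if self.w is not None and self.w <= 0:
            raise ValueError("w must be > 0")

    @property
    def has_qtl_component(self) -> bool:
        return self.qtl_source is not None

    @property
    def p_threshold(self) -> float | None:
        return None if self.t is None else 10.0 ** (-self.t)

    @property
    def name(self) -> str:
        base = f"{self.model}-50K"
        if self.qtl_source is None:
            return base
        suffix = f"+{self.qtl_source}QTL{self.t}"
        if self.n is not None:
            w = int(self.w) if float(self.w).is_integer() else self.w
            suffix += f"-{self.n}/{w}"
        return base + suffix

    def __str__(self) -> str:
        return self.name


def parse_scenario(name: str) -> ScenarioSpec:
    """Parse a scenario acronym; ``parse_scenario(s).name == s`` for canonical names."""
    if not name:
        raise ValueError(f"empty scenario name; expected {_GRAMMAR_HELP}")
    m = _GRAMMAR.match(name.strip())
    if m is None:
        raise ValueError(f"malformed scenario name {name!r}; expected {_GRAMMAR_HELP}")
    d = m.groupdict()
    return ScenarioSpec(
        model=d["model"],
        qtl_source=d["source"],
        t=int(d["t"]) if d["t"] else None,
        n=int(d["n"]) if d["n"] else None,
        w=float(d["w"]) if d["w"] else None,
    )
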