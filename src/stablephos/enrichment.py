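"""Overrepresentation and odds-ratio testing against annotation term sets.

Generic machinery: a foreground set (e.g. stable sites or their host genes)
is tested against a background for enrichment in user-supplied annotation
terms with Fisher's exact test, and 2x2 count tables are tested for departure
from odds ratio 1 with the Woolf (log-OR normal approximation) test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = foreground & annotated, b = foreground not annotated,
    c = background & annotated, d = background not annotated."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AnnotationSet:
    """A named annotation term and its member identifiers."""

    term: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation term {self.term!r} has no members")


def fisher_test(table: ContingencyTable, alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; returns (sample odds ratio, p).

    The sample odds ratio is ad/bc (inf when bc = 0 and ad > 0; nan for 0/0).
    """
    a, b, c, d = table.counts
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    else:
        odds = math.nan if num == 0 else math.inf
    return odds, float(p)


def fisher_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    terms: Sequence[AnnotationSet],
    alternative: str = "greater",
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-term overrepresentation of ``foreground`` within ``background``.

    The contingency table for each term counts foreground members against the
    background *excluding* the foreground. One-sided "greater" by default
    (overrepresentation); Benjamini-Hochberg adjusted p-values across terms
    when ``adjust`` is true.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        extra = sorted(fg - bg)[:5]
        raise ValueError(f"foreground is not a subset of background (e.g. {extra})")
    rest = bg - fg
    rows = []
    for t in terms:
        a = len(fg & t.members)
        b = len(fg) - a
        c = len(rest & t.members)
        d = len(rest) - c
        table = ContingencyTable(a, b, c, d)
        odds, p = fisher_test(table, alternative=alternative)
        rows.append(
            {"term": t.term, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "odds_ratio", "p"])
    if adjust and len(df):
        df["p_adj"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    return df


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool  # Haldane-Anscombe +0.5 applied


def odds_ratio_test(table: ContingencyTable, conf_level: float = 0.95) -> OddsRatioResult:
    """Odds ratio ad/bc with Woolf approximation CI and null OR = 1 test.

    CI: exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)); p: two-sided normal on
    ln OR / SE. Zero cells receive the Haldane-Anscombe correction (+0.5 to
    every cell, logged); two zeros in the same row or column leave the odds
    ratio undefined and raise.
    """
    if not (0 < conf_level < 1):
        raise ValueError("conf_level must be in (0, 1)")
    a, b, c, d = table.counts
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("odds ratio undefined: two zero cells share a row or column")
    corrected = min(a, b, c, d) == 0
    if corrected:
        logger.warning(
            "zero cell in %s: applying Haldane-Anscombe +0.5 correction", table.counts
        )
        af, bf, cf, df_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df_ = float(a), float(b), float(c), float(d)
    odds = (af * df_) / (bf * cf)
    se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df_)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    log_or = math.log(odds)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = float(2.0 * stats.norm.sf(abs(log_or) / se))
    return OddsRatioResult(
        odds_ratio=odds, ci_low=ci_low, ci_high=ci_high, p=min(p, 1.0), corrected=corrected
    )


def read_annotation_sets(path: Union[str, Path], fmt: str | None = None) -> list[AnnotationSet]:
    """Read annotation terms from a two-column TSV (term<TAB>member) or a GMT
    file (term<TAB>description<TAB>member...). Format inferred from the
    extension when ``fmt`` is None."""
    path = Path(path)
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    members: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if fmt == "gmt":
                if len(parts) < 3:
                    raise ValueError(f"{path}:{line_no}: GMT line needs >= 3 fields")
                term, _desc, *items = parts
                members.setdefault(term, set()).update(x for x in items if x)
            else:
                if len(parts) != 2:
                    raise ValueError(f"{path}:{line_no}: expected 'term<TAB>member'")
                term, member = parts
                members.setdefault(term, set()).add(member)
    return [AnnotationSet(term=t, members=frozenset(m)) for t, m in members.items()]
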