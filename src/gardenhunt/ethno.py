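"""Interview-based hunting scope indexes.

Semi-structured interviews yield, per respondent, a list of game taxa they
target and an ordered list (up to three) of preferred taxa.  Two indexes
summarize the citations, both rescaled by the number of informants to
correct for sample size:

* hunting importance  Hv = (h / n) * N, where h is the number of times a
  taxon is cited as a target, n the total target citations over all taxa,
  and N the number of respondents;
* hunting preference  Pv = (p / n') * N', where p counts first-choice
  citations, and n' and N' are the citation and respondent totals among
  respondents who expressed any preference (no-preference answers are
  excluded).

Ambiguous vernacular names (e.g. the two brocket deer, the two long-nosed
armadillos) are resolved by a vernacular-to-taxon map, typically collapsing
them to genus level; a respondent's repeated mention of one taxon counts
once.  Summed over distinct taxa, Hv equals N exactly when every citation
maps to a listed taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CitationCounts",
    "tally_citations",
    "hv",
    "pv",
    "indices_table",
    "read_interviews",
    "split_multi",
]

MULTI_SEP = ";"


def split_multi(value) -> list[str]:
    """Split a semicolon-separated multi-response field into clean items."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    return [s.strip() for s in str(value).split(MULTI_SEP) if s.strip()]


@dataclass
class CitationCounts:
    """Per-taxon citation tallies from an interview set."""

    h: dict[str, int] = field(default_factory=dict)  # target citations
    p: dict[str, int] = field(default_factory=dict)  # first-choice citations
    n: int = 0            # total target citations over all taxa
    n_pref: int = 0       # total preference citations (respondents with >=1)
    N: int = 0            # respondents interviewed
    N_pref: int = 0       # respondents expressing >=1 preference


def _map_taxa(names: Iterable[str], taxonomy_map: Mapping[str, str] | None) -> list[str]:
    out = []
    for nm in names:
        if taxonomy_map is None:
            out.append(nm)
        elif nm in taxonomy_map:
            out.append(taxonomy_map[nm])
        else:
            raise ValueError(f"unmapped vernacular name: {nm!r}")
    return out


def tally_citations(
    interviews: pd.DataFrame,
    taxonomy_map: Mapping[str, str] | None = None,
) -> CitationCounts:
    """Tally target and first-preference citations at mapped-taxon level.

    ``interviews`` holds one row per respondent with semicolon-separated
    ``cited_taxa`` and ``ranked_preferences`` columns (the first ranked item
    is the first choice).  Each mention maps through ``taxonomy_map``;
    mentions of distinct vernaculars that map to the same taxon (e.g. the
    two brocket deer to one genus) each count, but a literal repeat of the
    same vernacular by one respondent counts once.
    """
    counts = CitationCounts(N=len(interviews))
    for _, row in interviews.iterrows():
        cited = list(dict.fromkeys(split_multi(row.get("cited_taxa"))))
        mapped = _map_taxa(cited, taxonomy_map)
        for t in mapped:
            counts.h[t] = counts.h.get(t, 0) + 1
            counts.n += 1
        prefs = split_multi(row.get("ranked_preferences"))
        unknown = [x for x in prefs if x not in cited]
        if unknown:
            raise ValueError(
                f"ranked preference not among cited taxa for respondent "
                f"{row.get('respondent_id', '?')}: {unknown}"
            )
        if prefs:
            counts.N_pref += 1
            counts.n_pref += len(prefs)
            first = _map_taxa(prefs[:1], taxonomy_map)[0]
            counts.p[first] = counts.p.get(first, 0) + 1
    return counts


def hv(counts: CitationCounts, taxon: str) -> float:
    """Hunting importance of a taxon: (h / n) * N."""
    if counts.n == 0:
        raise ValueError("no target citations: Hv undefined")
    return counts.h.get(taxon, 0) / counts.n * counts.N


def pv(counts: CitationCounts, taxon: str) -> float:
    """Hunting preference of a taxon: (p / n') * N' over preference-givers."""
    if counts.n_pref == 0:
        raise ValueError("no preference citations: Pv undefined")
    return counts.p.get(taxon, 0) / counts.n_pref * counts.N_pref


def indices_table(counts: CitationCounts) -> pd.DataFrame:
    """Per-taxon table of h, Hv, p, Pv sorted by descending Hv.

    A taxon never cited as first choice gets an empty Pv cell (NA), the way
    such tables are conventionally printed.
    """
    rows = []
    for taxon in sorted(counts.h, key=lambda t: (-counts.h[t], t)):
        p = counts.p.get(taxon, 0)
        rows.append(
            {
                "taxon": taxon,
                "h": counts.h[taxon],
                "Hv": hv(counts, taxon),
                "p": p,
                "Pv": pv(counts, taxon) if (p and counts.n_pref) else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=["taxon", "h", "Hv", "p", "Pv"])


def read_interviews(path) -> pd.DataFrame:
    """interviews.csv: one row per respondent, ';'-separated multi fields."""
    df = pd.read_csv(path, dtype=str)
    if "respondent_id" not in df.columns:
        raise ValueError("interviews table needs a respondent_id column")
    return df
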