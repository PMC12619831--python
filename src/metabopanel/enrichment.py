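"""Over-representation analysis (ORA) of a selected metabolite list.

One-sided hypergeometric upper-tail test of each user-supplied metabolite
set against the selection, within an explicit universe (by default, the
metabolites that survived preprocessing — the tested sampling frame). The
enrichment ratio is observed/expected hits:

    ratio = n_hits / (n_selected * set_size / universe_size)

Benjamini-Hochberg FDR is applied across the tested sets. Set definitions
are read from GMT files (tab-separated: name, description, members...).
Database content (pathway catalogs) is deliberately out of scope: sets are
always user-supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .univariate import bh_fdr


class EnrichmentError(ValueError):
    pass


class GMTFormatError(EnrichmentError):
    pass


@dataclass(frozen=True)
class MetaboliteSet:
    set_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise EnrichmentError(f"set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise EnrichmentError(f"set {self.set_id!r} has duplicate members")


@dataclass
class ORAResult:
    set_id: str
    name: str
    n_hits: int
    n_selected: int
    set_size: int
    universe_size: int
    enrichment_ratio: float
    p_value: float
    q_value: float


def ora(selected: Iterable[str], sets: Sequence[MetaboliteSet],
        universe: Iterable[str]) -> list[ORAResult]:
    """Hypergeometric over-representation of ``selected`` in each set.

    Sets are intersected with the universe before testing; sets with an
    empty intersection are dropped. Results are sorted by p-value.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise EnrichmentError("empty selection")
    if not universe:
        raise EnrichmentError("empty universe")
    stray = selected - universe
    if stray:
        raise EnrichmentError(f"selected ids outside the universe: {sorted(stray)[:5]}")
    n_univ, n_sel = len(universe), len(selected)
    results = []
    for s in sets:
        members = set(s.members) & universe
        if not members:
            continue
        k = len(members & selected)
        m = len(members)
        p = float(hypergeom.sf(k - 1, n_univ, m, n_sel))
        expected = n_sel * m / n_univ
        results.append(ORAResult(s.set_id, s.name, k, n_sel, m, n_univ,
                                 k / expected, p, float("nan")))
    if results:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def read_gmt(path) -> list[MetaboliteSet]:
    """Parse a GMT file (LF or CRLF); duplicate members are deduplicated
    with a warning; lines with fewer than 3 fields are an error."""
    sets = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\r").split("\t")
        if len(fields) < 3:
            raise GMTFormatError(
                f"{path}: line {lineno} has {len(fields)} fields (need >= 3)"
            )
        name, desc, *members = fields
        members = [m for m in members if m]
        deduped = list(dict.fromkeys(members))
        if len(deduped) != len(members):
            warnings.warn(f"{path}: line {lineno}: duplicate members removed",
                          stacklevel=2)
        sets.append(MetaboliteSet(name, desc or name, tuple(deduped)))
    return sets


def write_gmt(sets: Sequence[MetaboliteSet], path) -> None:
    lines = ["\t".join([s.set_id, s.name, *s.members]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")
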