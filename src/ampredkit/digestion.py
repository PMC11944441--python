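"""Rule-based protease digestion and AMP-domain release assessment.

Cleavage specificity is expressed as a zero-width regular expression evaluated
between residues: a rule matches at position ``p`` (1-based, cut between
residues ``p`` and ``p+1``) when the pattern matches the inter-residue gap --
lookbehind describes P1 and earlier, lookahead P1' and later, so the classic
trypsin rule "after K/R unless the next residue is proline" is simply
``(?<=[KR])(?!P)``.  Termini are never cleavage sites.

A matched AMP-like domain is *releasable* when a cleavage site exists at or
within ``window`` residues of each flank (a flank at the protein terminus is
already free).  The default window of 10 residues reflects how close a site
must be for the liberated fragment to retain the domain essentially intact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .io import PeptideRecord


@dataclass(frozen=True)
class ProteaseRule:
    """One enzyme's cleavage specificity as a zero-width regex."""

    name: str
    site_pattern: str
    description: str = ""
    _regex: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_regex", re.compile(self.site_pattern))

    def matches_at(self, sequence: str, pos: int) -> bool:
        """True when the rule permits cleavage between residues pos, pos+1."""
        return _zero_width_match(self._regex, sequence, pos)

    def sites(self, sequence: str) -> list[int]:
        """Ascending internal cleavage positions (1-based, between p and p+1)."""
        return [
            p for p in range(1, len(sequence))
            if _zero_width_match(self._regex, sequence, p)
        ]


def _zero_width_match(regex: re.Pattern, sequence: str, pos: int) -> bool:
    m = regex.match(sequence, pos)
    return m is not None and m.end() == pos


def _rules_path() -> Path:
    return Path(str(resources.files("ampredkit").joinpath("data/protease_rules.tsv")))


def load_rules(path: str | Path | None = None) -> dict[str, ProteaseRule]:
    """Load the enzyme rule table (packaged TSV by default; user-editable)."""
    path = Path(path) if path is not None else _rules_path()
    rules: dict[str, ProteaseRule] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("enzyme\t"):
            raise ValueError(f"{path}: expected header starting with 'enzyme'")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed rule line: {line!r}")
            name = parts[0].strip().lower()
            rules[name] = ProteaseRule(
                name=name,
                site_pattern=parts[1],
                description=parts[2] if len(parts) > 2 else "",
            )
    return rules


def get_rule(name: str, rules: dict[str, ProteaseRule] | None = None) -> ProteaseRule:
    rules = rules if rules is not None else load_rules()
    key = name.strip().lower()
    if key not in rules:
        available = ", ".join(sorted(rules))
        raise KeyError(f"unknown enzyme {name!r}; available rules: {available}")
    return rules[key]


def list_cleavage_sites(
    protein: PeptideRecord | str, rule: ProteaseRule | str
) -> list[int]:
    """Ascending cleavage positions of one enzyme on one protein.

    Position ``p`` means cleavage between residues ``p`` and ``p+1``
    (1-based); termini are never sites.
    """
    seq = protein.sequence if isinstance(protein, PeptideRecord) else protein
    if isinstance(rule, str):
        rule = get_rule(rule)
    return [p for p in range(1, len(seq)) if _zero_width_match(rule._regex, seq, p)]


def digest(protein: PeptideRecord | str, rule: ProteaseRule | str) -> list[str]:
    """Fragments produced by complete digestion; they reassemble the input."""
    seq = protein.sequence if isinstance(protein, PeptideRecord) else protein
    sites = list_cleavage_sites(seq, rule)
    bounds = [0] + sites + [len(seq)]
    return [seq[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass(frozen=True)
class DomainReleaseReport:
    """Cleavage-site availability around a matched domain's flanks."""

    protein_id: str
    domain_start: int
    domain_end: int
    window: int
    upstream_sites: tuple[tuple[int, str], ...]  # (position, enzyme)
    downstream_sites: tuple[tuple[int, str], ...]
    releasable: bool
    n_terminal_free: bool = False
    c_terminal_free: bool = False


def assess_domain_release(
    protein: PeptideRecord,
    domain_start: int,
    domain_end: int,
    rules: list[ProteaseRule] | None = None,
    window: int = 10,
) -> DomainReleaseReport:
    """Decide whether digestion could liberate the matched domain.

    The domain is releasable when each flank either sits at a protein
    terminus or has a cleavage site within ``window`` residues: upstream
    sites at positions ``domain_start - 1 - window .. domain_start - 1``
    (cut at ``domain_start - 1`` is directly flanking), downstream sites at
    ``domain_end .. domain_end + window``.  Sites from all supplied rules are
    pooled, and each flanking site is attributed to its enzyme(s).
    """
    n = protein.length
    if not (1 <= domain_start <= domain_end <= n):
        raise ValueError(
            f"domain coordinates {domain_start}..{domain_end} out of range 1..{n}"
        )
    if rules is None:
        rules = [get_rule("trypsin")]

    upstream: list[tuple[int, str]] = []
    downstream: list[tuple[int, str]] = []
    for rule in rules:
        for p in list_cleavage_sites(protein, rule):
            if domain_start - 1 - window <= p <= domain_start - 1:
                upstream.append((p, rule.name))
            if domain_end <= p <= domain_end + window:
                downstream.append((p, rule.name))
    upstream.sort()
    downstream.sort()

    n_free = domain_start == 1
    c_free = domain_end == n
    releasable = (n_free or bool(upstream)) and (c_free or bool(downstream))
    return DomainReleaseReport(
        protein_id=protein.id,
        domain_start=domain_start,
        domain_end=domain_end,
        window=window,
        upstream_sites=tuple(upstream),
        downstream_sites=tuple(downstream),
        releasable=releasable,
        n_terminal_free=n_free,
        c_terminal_free=c_free,
    )
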