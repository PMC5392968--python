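"""Post-processing of ranked predictions.

Three rules run in sequence on a scored prediction list:

1. **Age check tags.**  Age-group check tags are hard for
   similarity-driven candidate sources (a paediatric article's
   neighbours often discuss adults), so explicit age mentions in the
   abstract are detected — numbers near the word "age"/"aged"/"ages",
   with year/month units and ranges — and mapped through configurable
   age-bracket rules.  Detected tags missing from the list are
   injected at its head.
2. **Specificity pruning.**  Indexing prefers the most specific
   applicable heading, so a term is dropped when one of its hierarchy
   descendants is ranked strictly higher.
3. **Score cutoff.**  After capping at N terms, the list is truncated
   at the first position i ≥ 2 where the next score collapses:
   S_{i+1} < S_i · ln(i) · λ.  The log factor makes the rule laxer
   deeper in the list, where score differences are subtler.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .corpus import Document
from .ranker import PredictionList, ScoredTerm
from .vocabulary import Vocabulary

#: Score margin above the current maximum for injected check tags.
_INJECT_EPS = 1e-6


@dataclass
class PruningConfig:
    lambda_cut: float = 0.3
    n_cap: int = 25
    min_keep: int = 1

    def __post_init__(self):
        if self.lambda_cut <= 0:
            raise ValueError("lambda_cut must be positive")
        if not self.n_cap >= self.min_keep >= 1:
            raise ValueError("need n_cap >= min_keep >= 1")


@dataclass
class AgeBracket:
    """One age rule: [min_months, max_months] → check-tag descriptor."""

    min_months: float
    max_months: float  # inf for open-ended
    check_tag: str


@dataclass
class AgeRule:
    """Ordered age brackets; the first matching bracket wins.

    Listing more specific brackets first makes the effective ranges
    disjoint even when nominal endpoints overlap (e.g. a broad adult
    bracket after a young-adult one).
    """

    brackets: list[AgeBracket] = field(default_factory=list)
    window: int = 60  # chars scanned either side of an age keyword

    def lookup(self, months: float) -> str | None:
        for b in self.brackets:
            if b.min_months <= months <= b.max_months:
                return b.check_tag
        return None


#: Conventional age-bracket names and ranges (months), most specific
#: first where nominal ranges overlap.
DEFAULT_AGE_BRACKETS: list[tuple[str, float, float]] = [
    ("Infant, Newborn", 0, 1),
    ("Infant", 1, 23),
    ("Child, Preschool", 24, 71),
    ("Child", 72, 155),
    ("Adolescent", 156, 227),
    ("Young Adult", 228, 299),
    ("Adult", 228, 539),
    ("Aged, 80 and over", 960, math.inf),
    ("Aged", 780, math.inf),
    ("Middle Aged", 540, 779),
]


def default_age_rules(vocab: Vocabulary) -> AgeRule:
    """Build the default rule set against *vocab*.

    Brackets resolve check-tag names to descriptor ids by preferred
    name; names absent from the vocabulary are dropped, so toy
    vocabularies carrying only a few age tags still work.
    """
    by_name = {d.preferred_name: d.descriptor_id for d in vocab.descriptors.values()}
    brackets = [
        AgeBracket(min_months=lo, max_months=hi, check_tag=by_name[name])
        for name, lo, hi in DEFAULT_AGE_BRACKETS
        if name in by_name
    ]
    return AgeRule(brackets=brackets)


_AGE_KEYWORD_RE = re.compile(r"\b(ages?|aged)\b", re.IGNORECASE)
_NUMBER_RE = re.compile(
    r"(\d+)(?:\s*(?:-|–|to)\s*(\d+))?\s*(years?|yrs?|months?|mos?)?",
    re.IGNORECASE,
)


def detect_age_checktags(abstract: str, rules: AgeRule) -> set[str]:
    """Age check tags implied by explicit age mentions in *abstract*.

    Scans a ±window character span around each "age"/"aged"/"ages"
    occurrence for integers (ranges contribute both endpoints, a
    following unit word selects months vs the year default) and maps
    each age through the bracket rules.
    """
    found: set[str] = set()
    for kw in _AGE_KEYWORD_RE.finditer(abstract):
        lo = max(0, kw.start() - rules.window)
        hi = min(len(abstract), kw.end() + rules.window)
        window = abstract[lo:hi]
        for m in _NUMBER_RE.finditer(window):
            unit = (m.group(3) or "years").lower()
            factor = 1.0 if unit.startswith("mo") else 12.0
            endpoints = [float(m.group(1))]
            if m.group(2) is not None:
                endpoints.append(float(m.group(2)))
            for val in endpoints:
                tag = rules.lookup(val * factor)
                if tag is not None:
                    found.add(tag)
    return found


def specificity_prune(pred: PredictionList, vocab: Vocabulary) -> PredictionList:
    """Drop terms out-ranked by one of their hierarchy descendants.

    A term survives unless some strictly higher-ranked prediction is
    its descendant (any depth); survivor order is unchanged.
    """
    ids = pred.ids()
    rank = {did: i for i, did in enumerate(ids)}
    keep = []
    for i, item in enumerate(pred.items):
        descendants = vocab.descendants(item.descriptor_id)
        if not any(rank.get(d, len(ids)) < i for d in descendants):
            keep.append(item)
    return PredictionList(doc_id=pred.doc_id, items=keep)


def score_cutoff(pred: PredictionList, cfg: PruningConfig | None = None) -> PredictionList:
    """Cap at n_cap, then truncate at the first collapsing score.

    Keeps positions 1..i for the smallest i ≥ 2 with
    S_{i+1} < S_i · ln(i) · λ; keeps everything (≤ n_cap) when no such
    i exists, and never fewer than min_keep.
    """
    cfg = cfg or PruningConfig()
    items = pred.items[: cfg.n_cap]
    cut = len(items)
    for i in range(2, len(items)):  # i is 1-based position; check S_{i+1}
        s_i = items[i - 1].score
        s_next = items[i].score
        if s_next < s_i * math.log(i) * cfg.lambda_cut:
            cut = i
            break
    cut = max(cut, min(cfg.min_keep, len(items)))
    return PredictionList(doc_id=pred.doc_id, items=items[:cut])


def postprocess(
    pred: PredictionList,
    doc: Document,
    vocab: Vocabulary,
    age_rules: AgeRule | None = None,
    pruning: PruningConfig | None = None,
) -> PredictionList:
    """Full post-processing pipeline (idempotent on its own output).

    Order: inject detected age check tags at the list head (score just
    above the current maximum, so the cutoff cannot immediately drop
    them), prune out-ranked ancestors, apply the score cutoff.
    """
    age_rules = age_rules if age_rules is not None else default_age_rules(vocab)
    pruning = pruning or PruningConfig()

    detected = detect_age_checktags(doc.abstract, age_rules)
    present = set(pred.ids())
    missing = sorted(detected - present)
    items = list(pred.items)
    if missing:
        top = max((it.score for it in items), default=0.0)
        items = [
            ScoredTerm(descriptor_id=did, score=top + _INJECT_EPS)
            for did in missing
        ] + items
    staged = PredictionList(doc_id=pred.doc_id, items=items)
    staged = specificity_prune(staged, vocab)
    return score_cutoff(staged, pruning)
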