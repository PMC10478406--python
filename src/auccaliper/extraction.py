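"""Extraction of AUC values from abstract text.

Abstracts report discrimination statistics in dense, semi-structured
prose: "The AUC was 0.704 (95% CI 0.603 to 0.806)", "AUROC of 85%",
"sensitivity 0.91, specificity 0.66, AUC 0.83". The extractor locates
cue phrases for the AUC family (AUC, AUROC, area under the ROC curve,
c-statistic, c-index, concordance index), associates nearby numbers with
the nearest preceding statistic cue, classifies confidence-interval
triplets into point / lower / upper roles, and applies guards against
the classic traps:

* pharmacokinetic AUCs, which carry units ("AUC0-24 was 412 ng·h/mL");
* lists of other statistics (sensitivity, specificity, Brier score ...)
  whose numbers must not be claimed by an AUC cue further left;
* sentences that define the AUC scale rather than report a result
  ("The AUC ranges between 0.5 and 1");
* out-of-range values: after percent conversion anything < 0 or >= 1 is
  dropped, including values of exactly 1, which cannot be reliably told
  apart from scale descriptions.

The design is deliberately conservative — when a number is ambiguous we
would rather miss a valid AUC than include an invalid one — and every
rejected candidate is logged with a machine-readable reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from .config import DEFAULT_CONFIG, ExtractionConfig, PipelineConfig

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import AbstractRecord

__all__ = [
    "CueMention",
    "AUCMatch",
    "RejectedCandidate",
    "CandidateRejected",
    "find_cue_mentions",
    "extract_values",
    "normalize_value",
    "decimal_places",
]

# 1:1 character normalization: unicode dashes/minus to '-', NBSP to ' '.
_CHAR_MAP = str.maketrans({"–": "-", "—": "-", "−": "-", " ": " "})

_NUM = r"[-+]?\d+(?:\.\d+)?(?:\s?%)?"
_NUM_RE = re.compile(r"(?<![\w.%])([-+]?\d+(?:,\d{3})+(?:\.\d+)?|[-+]?\d+(?:\.\d+)?)(\s?%)?")
_CI_TXT = r"(?:\d{2}(?:\.\d+)?\s?%\s*)?(?:CIs?|[Cc]onfidence [Ii]ntervals?)[:,]?\s*"
_TRIPLET_RE = re.compile(
    rf"({_NUM})\s*[\(\[]\s*(?:{_CI_TXT})?({_NUM})\s*(?:to|[-,;])\s*({_NUM})\s*[\)\]]"
)
_PAIR_RE = re.compile(rf"[\(\[]?\s*{_CI_TXT}({_NUM})\s*(?:to|[-,;])\s*({_NUM})\s*[\)\]]?")
_CI_LEVEL_RE = re.compile(r"^\s*%?\s*(?:CIs?\b|[Cc]onfidence)")
_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9“\"(\[])")
# Subscript suffixes marking pharmacokinetic AUCs: AUC0-24, AUC(0-t), AUCinf ...
_PK_SUFFIX_RE = re.compile(r"^(?:\d|\(|inf\b|last\b|tau\b|ss\b|[₀-₉∞])")


@dataclass(frozen=True)
class CueMention:
    """One occurrence of an AUC-family cue in a section's text."""

    cue: str
    canonical_cue: str
    char_start: int
    char_end: int
    section_label: str = ""
    pk_suffix: bool = False  # acronym carries a pharmacokinetic subscript


@dataclass(frozen=True)
class AUCMatch:
    """One extracted AUC value, normalized to a fraction in [0, 1)."""

    pmid: str
    value: float
    raw_token: str
    role: str  # point | ci_lower | ci_upper
    decimal_places: int
    was_percent: bool
    section_label: str = ""
    char_start: int = -1
    anomaly_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RejectedCandidate:
    pmid: str
    raw_token: str
    reason: str
    section_label: str = ""
    char_start: int = -1


class CandidateRejected(Exception):
    """A numeric token failed normalization or a guard."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


# ---------------------------------------------------------------------------
# Cues
# ---------------------------------------------------------------------------

def _phrase_regex(cfg: ExtractionConfig) -> list[tuple[re.Pattern, str]]:
    pats = []
    for canonical, phrases in cfg.phrase_cues.items():
        for p in sorted(phrases, key=len, reverse=True):
            pats.append((re.compile(rf"(?<!\w){re.escape(p)}(?!\w)", re.IGNORECASE), canonical))
    return pats


def _acronym_regex(cfg: ExtractionConfig) -> list[tuple[re.Pattern, str]]:
    pats = []
    for canonical, acrs in cfg.acronym_cues.items():
        for a in sorted(acrs, key=len, reverse=True):
            # case-sensitive; allow plural "AUCs"; capture what follows for
            # the pharmacokinetic-subscript check
            pats.append((re.compile(rf"(?<![A-Za-z0-9]){re.escape(a)}s?"), canonical))
    return pats


def find_cue_mentions(
    section_text: str,
    section_label: str = "",
    config: PipelineConfig | ExtractionConfig = DEFAULT_CONFIG,
) -> list[CueMention]:
    """All non-overlapping AUC-family cue occurrences, in document order.

    Phrase cues are matched case-insensitively, bare acronyms
    case-sensitively. Where matches overlap (e.g. "area under the curve"
    inside the full ROC phrase) the longest, earliest-starting match
    wins. Acronyms immediately followed by a subscript (AUC0-24, AUCinf)
    are still reported but flagged ``pk_suffix``; downstream value
    extraction rejects numbers claimed by such cues.
    """
    cfg = config.extraction if isinstance(config, PipelineConfig) else config
    text = section_text.translate(_CHAR_MAP)
    raw: list[tuple[int, int, str, str, bool]] = []
    for pat, canonical in _phrase_regex(cfg):
        for m in pat.finditer(text):
            raw.append((m.start(), m.end(), m.group(0), canonical, False))
    for pat, canonical in _acronym_regex(cfg):
        for m in pat.finditer(text):
            pk = bool(_PK_SUFFIX_RE.match(text[m.end():]))
            raw.append((m.start(), m.end(), m.group(0), canonical, pk))
    raw.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    out: list[CueMention] = []
    last_end = -1
    for start, end, cue, canonical, pk in raw:
        if start < last_end:
            continue
        out.append(
            CueMention(
                cue=cue,
                canonical_cue=canonical,
                char_start=start,
                char_end=end,
                section_label=section_label,
                pk_suffix=pk,
            )
        )
        last_end = end
    return out


def _competing_mentions(text: str, cfg: ExtractionConfig) -> list[tuple[int, int, str]]:
    out = []
    for cue in cfg.competing_cues:
        for m in re.finditer(rf"(?<!\w){re.escape(cue)}(?!\w)", text, re.IGNORECASE):
            out.append((m.start(), m.end(), cue))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Token-level helpers
# ---------------------------------------------------------------------------

def decimal_places(raw_token: str) -> int:
    """Digits after the decimal point as printed.

    Percent tokens get two extra places so that "80%" (which normalizes
    to 0.80) is comparable with "0.80": both report two effective
    decimals.
    """
    tok = raw_token.strip()
    is_percent = tok.endswith("%")
    tok = tok.rstrip("%").strip().replace(",", "")
    if "." in tok:
        places = len(tok.split(".", 1)[1])
    else:
        places = 0
    return places + 2 if is_percent else places


def normalize_value(raw_token: str, percent_context: bool = False) -> tuple[float, bool]:
    """Normalize a printed token to a fraction in [0, 1).

    Tokens with an explicit percent sign are divided by 100. A bare
    number in (1, 100] is treated as a percent only when the surrounding
    sentence gives percent context; otherwise it is rejected rather than
    silently rescaled. After conversion, values < 0 or >= 1 are rejected
    (so an AUC printed as exactly 1 is dropped).

    Raises :class:`CandidateRejected` with a reason code on rejection.
    """
    tok = raw_token.strip()
    is_percent = tok.endswith("%")
    numeric = tok.rstrip("%").strip().replace(",", "")
    try:
        value = float(numeric)
    except ValueError:
        raise CandidateRejected("not_numeric") from None
    was_percent = False
    if is_percent:
        value /= 100.0
        was_percent = True
    elif value > 1.0:
        if percent_context and value <= 100.0:
            value /= 100.0
            was_percent = True
        else:
            raise CandidateRejected("out_of_range")
    if value < 0.0 or value >= 1.0:
        raise CandidateRejected("out_of_range")
    return value, was_percent


def _unit_regex(cfg: ExtractionConfig) -> re.Pattern:
    units = "|".join(re.escape(u) for u in sorted(cfg.unit_suffixes, key=len, reverse=True))
    # "412 ng·h/mL", "38 µg*h/ml", "12 h", "0.8 mg·h/L", "5 /mL"
    return re.compile(
        rf"^\s*(?:(?:{units})\b[·*/]?|[·*]\s*(?:{units})\b|/\s*(?:{units})\b)",
        re.IGNORECASE,
    )


# ---------------------------------------------------------------------------
# Main extraction
# ---------------------------------------------------------------------------

@dataclass
class _Candidate:
    start: int
    end: int
    raw: str
    role: str = "point"
    partner_start: int = -1  # start offset of the sibling CI limit
    anchor_start: int = -1  # offset used for cue association (triplet point)
    flags: set[str] = field(default_factory=set)


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    spans = []
    pos = 0
    for m in _SENTENCE_SPLIT_RE.finditer(text):
        spans.append((pos, m.start()))
        pos = m.end()
    spans.append((pos, len(text)))
    return [s for s in spans if s[1] > s[0]]


def _interval_candidates(text: str) -> dict[int, _Candidate]:
    """Locate point (lower, upper) triplets and bare CI pairs.

    Returns a map from token start offset to a role-annotated candidate;
    numbers not covered here are standalone point candidates.
    """
    cands: dict[int, _Candidate] = {}
    consumed: list[tuple[int, int]] = []
    for m in _TRIPLET_RE.finditer(text):
        p, lo, hi = (m.group(i) for i in (1, 2, 3))
        p_s, lo_s, hi_s = (m.start(i) for i in (1, 2, 3))
        cands[p_s] = _Candidate(p_s, p_s + len(p), p, "point")
        cands[lo_s] = _Candidate(
            lo_s, lo_s + len(lo), lo, "ci_lower", partner_start=hi_s, anchor_start=p_s
        )
        cands[hi_s] = _Candidate(
            hi_s, hi_s + len(hi), hi, "ci_upper", partner_start=lo_s, anchor_start=p_s
        )
        consumed.append((m.start(), m.end()))
    for m in _PAIR_RE.finditer(text):
        if any(m.start() < e and m.end() > s for s, e in consumed):
            continue
        lo, hi = m.group(1), m.group(2)
        lo_s, hi_s = m.start(1), m.start(2)
        cands[lo_s] = _Candidate(lo_s, lo_s + len(lo), lo, "ci_lower", partner_start=hi_s)
        cands[hi_s] = _Candidate(hi_s, hi_s + len(hi), hi, "ci_upper", partner_start=lo_s)
    return cands


def extract_values(
    record: "AbstractRecord",
    config: PipelineConfig = DEFAULT_CONFIG,
    rejections: list[RejectedCandidate] | None = None,
) -> list[AUCMatch]:
    """Extract normalized AUC values from one abstract.

    Numbers are claimed by the nearest statistic cue to their left within
    the association window; only numbers claimed by a clean AUC cue
    survive. A cue may claim numbers in the following sentence only when
    that sentence introduces no statistic cue of its own. Rejected
    candidates are appended to ``rejections`` (if given) with a reason
    code: ``competing_cue``, ``pharmacokinetic_cue``, ``unit_suffix``,
    ``scale_definition``, ``no_cue``, ``out_of_range``, ``not_numeric``.
    """
    cfg = config.extraction
    unit_re = _unit_regex(cfg)
    scale_res = [re.compile(p, re.IGNORECASE) for p in cfg.scale_definition_patterns]
    matches: list[AUCMatch] = []

    def reject(label: str, tok: str, reason: str, start: int) -> None:
        if rejections is not None:
            rejections.append(
                RejectedCandidate(
                    pmid=record.pmid,
                    raw_token=tok,
                    reason=reason,
                    section_label=label,
                    char_start=start,
                )
            )

    for label, section_text in record.sections:
        text = section_text.translate(_CHAR_MAP)
        if not text.strip():
            continue
        auc_cues = find_cue_mentions(text, label, cfg)
        competing = _competing_mentions(text, cfg)
        # (position, kind, pk) for every statistic cue, kind in {auc, other}
        cue_events = [(c.char_start, c.char_end, "auc", c.pk_suffix) for c in auc_cues]
        cue_events += [(s, e, "other", False) for s, e, _ in competing]
        cue_events.sort()

        sentences = _sentence_spans(text)
        sent_index = {}
        for i, (s, e) in enumerate(sentences):
            for j in range(s, e):
                sent_index[j] = i
        sent_has_cue = [
            any(s <= cs < e for cs, _, _, _ in cue_events) for s, e in sentences
        ]
        sent_is_scale = []
        for s, e in sentences:
            chunk = text[s:e]
            has_auc = any(s <= c.char_start < e for c in auc_cues)
            sent_is_scale.append(has_auc and any(r.search(chunk) for r in scale_res))

        interval = _interval_candidates(text)
        percent_ctx = {i: "%" in text[s:e] or "percent" in text[s:e].lower()
                       for i, (s, e) in enumerate(sentences)}

        # collect all numeric tokens with section-level offsets
        tokens: list[_Candidate] = []
        seen_starts = set()
        for m in _NUM_RE.finditer(text):
            tok = m.group(0)
            start = m.start()
            if start in interval:
                c = interval[start]
                c.raw = tok if len(tok) >= len(c.raw) else c.raw
                tokens.append(c)
            else:
                tokens.append(_Candidate(start, m.end(), tok))
            seen_starts.add(start)

        emitted: dict[int, AUCMatch] = {}
        dropped_range: set[int] = set()
        for cand in tokens:
            si = sent_index.get(cand.start)
            if si is None:
                continue
            # confidence level of an interval ("95% CI") is not a value
            if _CI_LEVEL_RE.match(text[cand.end:]):
                continue
            if sent_is_scale[si]:
                reject(label, cand.raw, "scale_definition", cand.start)
                continue
            if unit_re.match(text[cand.end:]):
                reject(label, cand.raw, "unit_suffix", cand.start)
                continue
            # anchor: CI limits are claimed through their triplet's point
            anchor = cand.anchor_start if cand.anchor_start >= 0 else cand.start
            claiming = None
            for cs, ce, kind, pk in cue_events:
                if ce <= anchor and anchor - ce <= cfg.association_window:
                    cue_si = sent_index.get(cs)
                    if cue_si != si and (sent_has_cue[si] or si - cue_si > 1):
                        continue
                    claiming = (cs, ce, kind, pk)
            if claiming is None:
                reject(label, cand.raw, "no_cue", cand.start)
                continue
            _, _, kind, pk = claiming
            if kind == "other":
                reject(label, cand.raw, "competing_cue", cand.start)
                continue
            if pk:
                reject(label, cand.raw, "pharmacokinetic_cue", cand.start)
                continue
            try:
                value, was_percent = normalize_value(cand.raw, percent_ctx[si])
            except CandidateRejected as err:
                reject(label, cand.raw, err.reason, cand.start)
                dropped_range.add(cand.start)
                continue
            emitted[cand.start] = AUCMatch(
                pmid=record.pmid,
                value=value,
                raw_token=cand.raw.strip(),
                role=cand.role,
                decimal_places=decimal_places(cand.raw),
                was_percent=was_percent,
                section_label=label,
                char_start=cand.start,
                anomaly_flags=frozenset(cand.flags),
            )

        # post-pass: CI anomalies (reversed limits, dropped partners)
        for start, m in list(emitted.items()):
            cand = next(t for t in tokens if t.start == start)
            if cand.role == "point":
                continue
            flags = set(m.anomaly_flags)
            partner = emitted.get(cand.partner_start)
            if partner is None:
                if cand.partner_start in dropped_range:
                    flags.add("out_of_range_partner")
            else:
                lo = m.value if cand.role == "ci_lower" else partner.value
                hi = partner.value if cand.role == "ci_lower" else m.value
                if lo > hi:
                    flags.add("ci_reversed")
            if flags != set(m.anomaly_flags):
                emitted[start] = AUCMatch(
                    **{**m.__dict__, "anomaly_flags": frozenset(flags)}
                )
        matches.extend(v for _, v in sorted(emitted.items()))

    return matches


def matches_to_rows(matches: Iterable[AUCMatch]) -> list[dict]:
    """Flatten matches into rows for the extracted-values CSV."""
    return [
        {
            "pmid": m.pmid,
            "section_label": m.section_label,
            "value": m.value,
            "role": m.role,
            "decimal_places": m.decimal_places,
            "was_percent": m.was_percent,
            "raw_token": m.raw_token,
            "char_start": m.char_start,
            "anomaly_flags": ";".join(sorted(m.anomaly_flags)),
        }
        for m in matches
    ]
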