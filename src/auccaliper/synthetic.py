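"""Synthetic abstract corpora with known ground truth.

Threshold-excess detection can only be tested against data where the
truth is known, so this module generates corpora of PubMed-style
abstracts from an explicit generative model:

* a smooth base distribution of "true" AUC values on (0, 1) — by
  default a log-spline density (proportional to the exponential of a
  natural cubic spline on the same knot vector the analysis spline
  uses), unimodal with mode near 0.75, so that under the null the
  histogram is exactly representable by the smooth fit and residuals at
  the thresholds reflect sampling noise only;
* a *promotion* model of hacking: a value falling within ``delta`` below
  a threshold t is, with probability ``h``, replaced by a uniform draw
  from (t, t + eps] — the minimal mechanism producing the predicted
  signature of a deficit just below and an excess just above each
  threshold;
* realistic reporting styles — plain point values, point with 95% CI,
  percents, one-decimal values, values of exactly 1 — and decoy content:
  pharmacokinetic AUCs with units, sensitivity/specificity lists, and
  sentences defining the AUC scale.

Every rendered number is annotated in the ground truth with whether it
should be extracted and whether it should enter the default histogram,
enabling exact recall/precision scoring of the extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import AbstractRecord, write_pubmed_xml
from .distribution import HistogramSpec, spline_knots, natural_spline_basis
from .extraction import AUCMatch

__all__ = [
    "SyntheticConfig",
    "PlantedValue",
    "GroundTruth",
    "SyntheticCorpus",
    "sample_true_auc",
    "sample_true_aucs",
    "apply_promotion",
    "promote_values",
    "render_abstract",
    "generate_corpus",
    "generate_values",
    "score_extraction",
]

# Default log-spline base density: coefficients of intercept + 4-df
# natural spline basis on the analysis knot vector, shaped to a broad
# unimodal density with mode near 0.75 (matched to a truncated normal
# with sd 0.12). Any coefficient vector here yields a null that the
# df=4 Poisson spline smooth can represent exactly.
DEFAULT_BASE_COEF = (-18.111804, 46.336143, -59.811272, 62.362982, -23.339370)

STYLES = ("plain_point", "point_with_ci", "percent", "one_decimal", "exactly_one")
DECOYS = ("pharmacokinetic", "sens_spec_list", "scale_definition_sentence", "no_auc_filler")

_JOURNALS = (
    ("PLoS One", 0.15),
    ("Clinical Prediction Reports", 0.30),
    ("Journal of Medical Screening Research", 0.30),
    ("Diagnostic Modelling", 0.25),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions.

    ``values_per_abstract_p`` is the parameter of a geometric
    distribution on {1, 2, ...}; 0.35 gives median 2 values per abstract
    with quartiles 1 and 4. ``promotion_probability`` (h) is the chance
    that a value within ``promotion_window`` (delta) below a threshold
    is promoted into the ``landing_window`` (eps) above it.
    """

    n_abstracts: int = 5000
    values_per_abstract_p: float = 0.35
    base_family: str = "log_spline"  # or "scaled_beta"
    base_coef: tuple[float, ...] = DEFAULT_BASE_COEF
    beta_params: tuple[float, float, float, float] = (3.8, 3.0, 0.4, 0.6)  # a, b, loc, scale
    thresholds: tuple[float, ...] = (0.7, 0.8, 0.9)
    promotion_probability: float = 0.1
    promotion_window: float = 0.03
    landing_window: float = 0.01
    style_mix: dict[str, float] = field(
        default_factory=lambda: {
            "plain_point": 0.68,
            "point_with_ci": 0.22,
            "percent": 0.08,
            "one_decimal": 0.01,
            "exactly_one": 0.01,
        }
    )
    decoy_mix: dict[str, float] = field(
        default_factory=lambda: {
            "pharmacokinetic": 0.30,
            "sens_spec_list": 0.40,
            "scale_definition_sentence": 0.20,
            "no_auc_filler": 0.10,
        }
    )
    decoy_probability: float = 0.4
    frac_no_auc: float = 0.25
    frac_unstructured: float = 0.15
    frac_pk_study: float = 0.03
    frac_meta_analysis: float = 0.02
    frac_short_abstract: float = 0.01
    seed: int = 12345

    def __post_init__(self):
        for name, mix, keys in (
            ("style_mix", self.style_mix, STYLES),
            ("decoy_mix", self.decoy_mix, DECOYS),
        ):
            if set(mix) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if not (self.promotion_window > 0 and self.landing_window > 0):
            raise ValueError("promotion and landing windows must be positive")
        if not 0 <= self.promotion_probability <= 1:
            raise ValueError("promotion probability must be in [0, 1]")
        for t in self.thresholds:
            if abs(t * 100 - round(t * 100)) > 1e-9:
                raise ValueError(f"threshold {t} not on the 0.01 grid")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlantedValue:
    """Ground truth for one rendered AUC value."""

    pmid: str
    value: float  # as printed, normalized to a fraction
    role: str  # point | ci_lower | ci_upper
    style: str
    pre_promotion_value: float
    promoted: bool
    should_be_extracted: bool
    should_enter_histogram: bool
    section_label: str = "RESULTS"


@dataclass
class GroundTruth:
    values: list[PlantedValue] = field(default_factory=list)

    def extractable(self) -> list[PlantedValue]:
        return [v for v in self.values if v.should_be_extracted]

    def n_extractable_abstracts(self) -> int:
        return len({v.pmid for v in self.values if v.should_be_extracted})

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "pmid", "value", "role", "style", "pre_promotion_value",
            "promoted", "should_be_extracted", "should_enter_histogram",
            "section_label",
        ]
        return pd.DataFrame([asdict(v) for v in self.values], columns=cols)


@dataclass
class SyntheticCorpus:
    records: list[AbstractRecord]
    truth: GroundTruth
    xml: bytes


# ---------------------------------------------------------------------------
# Value layer
# ---------------------------------------------------------------------------

class _LogSplineBase:
    """Inverse-CDF sampler for density proportional to exp(spline(x))."""

    def __init__(self, coef: Sequence[float], n_grid: int = 4096):
        mids = HistogramSpec().midpoints
        knots = spline_knots(mids, 4)
        self.grid = np.linspace(1e-9, 1 - 1e-9, n_grid)
        B = np.column_stack(
            [np.ones(n_grid), natural_spline_basis(self.grid, knots=knots)]
        )
        dens = np.exp(B @ np.asarray(coef, dtype=float))
        cdf = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(self.grid))]
        )
        self.cdf = cdf / cdf[-1]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.interp(rng.random(n), self.cdf, self.grid)


def sample_true_aucs(n: int, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw n true AUC values from the smooth base distribution on (0, 1)."""
    if config.base_family == "log_spline":
        return _LogSplineBase(config.base_coef).sample(n, rng)
    if config.base_family == "scaled_beta":
        a, b, loc, scale = config.beta_params
        out = loc + scale * rng.beta(a, b, size=n)
        # resample the (measure-zero in practice) draws outside (0, 1)
        bad = (out <= 0) | (out >= 1)
        while bad.any():
            out[bad] = loc + scale * rng.beta(a, b, size=int(bad.sum()))
            bad = (out <= 0) | (out >= 1)
        return out
    raise ValueError(f"unknown base family {config.base_family!r}")


def sample_true_auc(config: SyntheticConfig, rng: np.random.Generator) -> float:
    return float(sample_true_aucs(1, config, rng)[0])


def promote_values(
    values: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized promotion: each value in (t - delta, t] is moved, with
    probability h, to a uniform draw from (t, t + eps]."""
    out = np.asarray(values, dtype=float).copy()
    promoted = np.zeros(out.shape, dtype=bool)
    h = config.promotion_probability
    for t in config.thresholds:
        eligible = (out > t - config.promotion_window) & (out <= t) & ~promoted
        fire = eligible & (rng.random(out.shape) < h)
        n_fire = int(fire.sum())
        if n_fire:
            # 1 - U in (0, 1] keeps the landing strictly above t
            out[fire] = t + config.landing_window * (1.0 - rng.random(n_fire))
            promoted[fire] = True
    return out, promoted


def apply_promotion(
    value: float, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[float, bool]:
    out, promoted = promote_values(np.array([value]), config, rng)
    return float(out[0]), bool(promoted[0])


def generate_values(
    n: int, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Base draws plus promotion: the value layer of the generator.

    Returns (values, promoted_mask). This is the fast path used by
    simulation studies that do not need rendered text.
    """
    base = sample_true_aucs(n, config, rng)
    return promote_values(base, config, rng)


# ---------------------------------------------------------------------------
# Text layer
# ---------------------------------------------------------------------------

_BACKGROUND = (
    "Early identification of patients at risk remains a clinical priority.",
    "Risk stratification tools are increasingly used at the point of care.",
    "Accurate prognostic information can guide treatment decisions.",
)
_METHODS = (
    "We developed a multivariable logistic regression model using routinely collected data from {n} patients.",
    "A prediction model was derived in a retrospective cohort of {n} adults and internally validated.",
    "Model discrimination was assessed with the area under the receiver operating characteristic curve.",
)
_CONCLUSIONS = (
    "The model showed promising discrimination and warrants external validation.",
    "These findings support further evaluation before clinical use.",
    "External validation in independent cohorts is needed.",
)
_FILLER_RESULTS = (
    "Baseline characteristics were similar between derivation and validation cohorts.",
    "Calibration was acceptable on visual inspection.",
)

_POINT_TEMPLATES = (
    "The AUC was {tok}.",
    "The model achieved an AUROC of {tok}.",
    "The c-statistic was {tok}.",
    "Discrimination was assessed by the area under the receiver operating characteristic curve, which was {tok}.",
    "The sensitivity was {sens}, the specificity was {spec}, and the AUC was {tok}.",
)
_CI_SEPS = ("to", "-", ",")

_PK_SENTENCES = (
    "The mean glucose AUC0-24 was {big} ng·h/mL.",
    "The AUCinf was {mid} µg·h/mL after a single oral dose.",
    "Dose-normalized AUC0-12 of {small} mg·h/L was observed.",
)
_SENS_SPEC_SENTENCES = (
    "Sensitivity, specificity and accuracy were {a}, {b} and {c}, respectively.",
    "The sensitivity was {a} and the specificity was {b} at the optimal cut-off.",
)
_SCALE_SENTENCES = (
    "The AUC ranges between 0.5 and 1.",
    "AUC values between 0.7 and 0.8 were considered acceptable and values above 0.8 good.",
)
_NO_AUC_FILLER = (
    "Recruitment was completed across four participating centres.",
    "Follow-up data were available for most participants.",
)


def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _fmt(v: float, dp: int) -> str:
    return f"{v:.{dp}f}"


def _render_value(value: float, style: str, rng: np.random.Generator):
    """Render one value in a style; returns (sentence, parts) where parts
    is a list of (printed_value, role, raw_token)."""
    if style == "plain_point":
        dp = int(_choice(rng, (2, 2, 3)))
        tok = _fmt(value, dp)
        tpl = _choice(rng, _POINT_TEMPLATES)
        sens, spec = rng.uniform(0.5, 0.99, 2)
        sentence = tpl.format(tok=tok, sens=f"{sens:.2f}", spec=f"{spec:.2f}")
        return sentence, [(float(tok), "point", tok)]
    if style == "point_with_ci":
        dp = 3
        tok = _fmt(value, dp)
        w = rng.uniform(0.03, 0.12)
        lo = _fmt(min(max(value - w, 0.001), 0.998), dp)
        hi = _fmt(min(max(value + w, float(lo) + 0.001), 0.999), dp)
        sep = _choice(rng, _CI_SEPS)
        joined = f"{lo} {sep} {hi}" if sep == "to" else f"{lo}{sep} {hi}" if sep == "," else f"{lo}{sep}{hi}"
        sentence = f"The AUC was {tok} (95% CI {joined})."
        return sentence, [
            (float(tok), "point", tok),
            (float(lo), "ci_lower", lo),
            (float(hi), "ci_upper", hi),
        ]
    if style == "percent":
        dp = int(_choice(rng, (0, 1)))
        tok = f"{value * 100:.{dp}f}%"
        sentence = _choice(rng, ("The AUC was {tok}.", "The model achieved an AUROC of {tok}.")).format(tok=tok)
        return sentence, [(float(tok.rstrip('%')) / 100.0, "point", tok)]
    if style == "one_decimal":
        tok = _fmt(value, 1)
        return f"The AUC was {tok}.", [(float(tok), "point", tok)]
    if style == "exactly_one":
        tok = _choice(rng, ("1", "1.0"))
        return f"The model achieved an AUC of {tok}.", [(float(tok), "point", tok)]
    raise ValueError(f"unknown style {style!r}")


def _render_decoy(decoy: str, rng: np.random.Generator) -> str:
    if decoy == "pharmacokinetic":
        return _choice(rng, _PK_SENTENCES).format(
            big=int(rng.integers(100, 900)),
            mid=f"{rng.uniform(5, 80):.1f}",
            small=f"{rng.uniform(0.1, 0.95):.2f}",
        )
    if decoy == "sens_spec_list":
        a, b, c = (f"{x:.2f}" for x in rng.uniform(0.5, 0.99, 3))
        return _choice(rng, _SENS_SPEC_SENTENCES).format(a=a, b=b, c=c)
    if decoy == "scale_definition_sentence":
        return _choice(rng, _SCALE_SENTENCES)
    if decoy == "no_auc_filler":
        return _choice(rng, _NO_AUC_FILLER)
    raise ValueError(f"unknown decoy {decoy!r}")


def render_abstract(
    values: Sequence[float],
    styles: Sequence[str],
    decoys: Sequence[str],
    rng: np.random.Generator,
    pmid: str = "90000000",
    journal: str = "Clinical Prediction Reports",
    year: int = 2018,
    pre_promotion: Sequence[float] | None = None,
    promoted: Sequence[bool] | None = None,
    structured: bool = True,
) -> tuple[AbstractRecord, list[PlantedValue]]:
    """Render one abstract and its ground truth.

    AUC sentences are placed in the RESULTS section (or an unlabelled
    body for unstructured abstracts); decoy sentences are interleaved in
    RESULTS. Eligibility flags follow the analysis rules: a value is
    extractable iff its printed form normalizes into [0, 1), and enters
    the default histogram iff it is additionally a point value printed
    with more than one decimal place.
    """
    pre_promotion = list(pre_promotion) if pre_promotion is not None else list(values)
    promoted = list(promoted) if promoted is not None else [False] * len(values)

    results_bits: list[str] = []
    truth: list[PlantedValue] = []
    label = "RESULTS" if structured else ""
    for v, style, pre, prom in zip(values, styles, pre_promotion, promoted):
        sentence, parts = _render_value(v, style, rng)
        results_bits.append(sentence)
        for printed, role, raw in parts:
            extractable = 0.0 <= printed < 1.0
            dp = len(raw.rstrip("%").split(".")[1]) if "." in raw else 0
            if raw.endswith("%"):
                dp += 2
            truth.append(
                PlantedValue(
                    pmid=pmid,
                    value=printed,
                    role=role,
                    style=style,
                    pre_promotion_value=pre if role == "point" else printed,
                    promoted=prom if role == "point" else False,
                    should_be_extracted=extractable,
                    should_enter_histogram=extractable and role == "point" and dp > 1,
                    section_label=label,
                )
            )
    for d in decoys:
        results_bits.append(_render_decoy(d, rng))
    if not results_bits:
        results_bits.append(_choice(rng, _FILLER_RESULTS))
    order = rng.permutation(len(results_bits))
    results = " ".join(results_bits[i] for i in order)

    background = _choice(rng, _BACKGROUND)
    methods = _choice(rng, _METHODS).format(n=int(rng.integers(120, 5000)))
    conclusions = _choice(rng, _CONCLUSIONS)
    if structured:
        sections = (
            ("BACKGROUND", background),
            ("METHODS", methods),
            ("RESULTS", results),
            ("CONCLUSIONS", conclusions),
        )
    else:
        sections = (("", f"{background} {methods} {results} {conclusions}"),)
    record = AbstractRecord(
        pmid=pmid,
        title="A prediction model for an adverse clinical outcome",
        sections=sections,
        year=year,
        journal=journal,
        mesh_terms=("Humans", "Prognosis", "ROC Curve"),
        publication_types=("Journal Article",),
    )
    return record, truth


def _special_record(kind: str, pmid: str, journal: str, year: int, rng) -> AbstractRecord:
    if kind == "pk_study":
        body = " ".join(_render_decoy("pharmacokinetic", rng) for _ in range(2))
        return AbstractRecord(
            pmid=pmid,
            title="Pharmacokinetics of a novel oral agent in healthy volunteers",
            sections=(("", f"We characterised drug exposure in a phase I study. {body}"),),
            year=year,
            journal=journal,
            mesh_terms=("Humans", "Pharmacokinetics", "Area Under Curve"),
            publication_types=("Journal Article", "Clinical Trial, Phase I"),
        )
    if kind == "meta_analysis":
        return AbstractRecord(
            pmid=pmid,
            title="Prediction models for outcome X: a meta-analysis",
            sections=(("", "We pooled published estimates of model discrimination across twelve cohort studies and summarised their reported performance without re-estimating any model."),),
            year=year,
            journal=journal,
            mesh_terms=("Humans",),
            publication_types=("Meta-Analysis",),
        )
    if kind == "short":
        return AbstractRecord(
            pmid=pmid,
            title="Erratum",
            sections=(("", "Correction to earlier report."),),
            year=year,
            journal=journal,
            mesh_terms=(),
            publication_types=("Published Erratum",),
        )
    raise ValueError(kind)


def generate_corpus(
    config: SyntheticConfig,
    xml_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> SyntheticCorpus:
    """Generate a full corpus: records, ground truth and MEDLINE XML.

    Fully deterministic given ``config.seed``. Abstract composition:
    a fraction are pharmacokinetic studies, meta-analyses, or
    ultra-short notes (excluded upstream, exercising the flow chart);
    a further fraction carry no AUC at all; the rest report 1+ AUC
    values in the configured style mix, with decoy sentences mixed in.
    """
    rng = np.random.default_rng(config.seed)
    records: list[AbstractRecord] = []
    truth = GroundTruth()
    style_names = list(config.style_mix)
    style_probs = np.array([config.style_mix[s] for s in style_names])
    decoy_names = list(config.decoy_mix)
    decoy_probs = np.array([config.decoy_mix[d] for d in decoy_names])
    journal_names = [j for j, _ in _JOURNALS]
    journal_probs = np.array([p for _, p in _JOURNALS])

    for i in range(config.n_abstracts):
        pmid = str(90000001 + i)
        journal = journal_names[int(rng.choice(len(journal_names), p=journal_probs))]
        year = int(rng.integers(2008, 2023))
        u = rng.random()
        if u < config.frac_pk_study:
            records.append(_special_record("pk_study", pmid, journal, year, rng))
            continue
        if u < config.frac_pk_study + config.frac_meta_analysis:
            records.append(_special_record("meta_analysis", pmid, journal, year, rng))
            continue
        if u < config.frac_pk_study + config.frac_meta_analysis + config.frac_short_abstract:
            records.append(_special_record("short", pmid, journal, year, rng))
            continue

        has_auc = rng.random() >= config.frac_no_auc
        decoys = []
        if rng.random() < config.decoy_probability:
            decoys.append(decoy_names[int(rng.choice(len(decoy_names), p=decoy_probs))])
        if has_auc:
            n_vals = int(rng.geometric(config.values_per_abstract_p))
            base = sample_true_aucs(n_vals, config, rng)
            vals, promoted = promote_values(base, config, rng)
            styles = [style_names[int(k)] for k in rng.choice(len(style_names), size=n_vals, p=style_probs)]
        else:
            vals, promoted, styles = np.array([]), np.array([], dtype=bool), []
            decoys.append("no_auc_filler")
        structured = rng.random() >= config.frac_unstructured
        rec, planted = render_abstract(
            vals,
            styles,
            decoys,
            rng,
            pmid=pmid,
            journal=journal,
            year=year,
            pre_promotion=base if has_auc else [],
            promoted=promoted,
            structured=structured,
        )
        records.append(rec)
        truth.values.extend(planted)

    xml = write_pubmed_xml(records, xml_path)
    if truth_path is not None:
        truth.to_dataframe().to_csv(truth_path, index=False)
    return SyntheticCorpus(records=records, truth=truth, xml=xml)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_extraction(
    matches: Sequence[AUCMatch],
    truth: GroundTruth,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """Recall and precision of extracted values against ground truth.

    Values are compared per abstract as multisets of (value, role)
    pairs; a planted value counts as recovered when an extracted match
    in the same abstract agrees in role and printed value. Recall is
    recovered/planted (over extraction-eligible planted values);
    precision is recovered/extracted.
    """
    from collections import Counter, defaultdict

    planted: dict[str, Counter] = defaultdict(Counter)
    for v in truth.extractable():
        planted[v.pmid][(round(v.value, 9), v.role)] += 1
    found: dict[str, Counter] = defaultdict(Counter)
    for m in matches:
        found[m.pmid][(round(m.value, 9), m.role)] += 1

    n_planted = sum(sum(c.values()) for c in planted.values())
    n_found = sum(sum(c.values()) for c in found.values())
    n_hit = 0
    for pmid, c in planted.items():
        overlap = c & found.get(pmid, Counter())
        n_hit += sum(overlap.values())
    recall = n_hit / n_planted if n_planted else 1.0
    precision = n_hit / n_found if n_found else 1.0
    return recall, precision
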