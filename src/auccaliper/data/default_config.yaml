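# Default cue/guard lists for AUC extraction and corpus-level exclusion
# indicators. These lists are data, not code: edit or override them with
# a custom config file rather than patching the extractor.
extraction:
  # Multi-word cues, matched case-insensitively, keyed by canonical name.
  phrase_cues:
    roc_area_phrase:
      - area under the receiver operating characteristic curve
      - area under the receiver operating characteristics curve
      - area under the roc curve
      - area under the curve
      - receiver operating characteristic curve
      - receiver operating characteristics curve
    c_statistic:
      - c-statistic
      - c statistic
    c_index:
      - c-index
      - c index
    concordance:
      - concordance index
      - concordance statistic
  # Bare acronyms, matched case-sensitively on word boundaries.
  acronym_cues:
    auc:
      - AUC
    auroc:
      - AUROC
      - AUROCC
  # Competing statistic cues: a number whose nearest preceding cue is one
  # of these is not an AUC value.
  competing_cues:
    - sensitivity
    - specificity
    - accuracy
    - brier score
    - brier
    - positive predictive value
    - negative predictive value
    - ppv
    - npv
    - f1 score
    - f1-score
    - youden
    - kappa
    - likelihood ratio
    - hazard ratio
    - odds ratio
    - risk ratio
    - relative risk
    - r-squared
    - p-value
    - p value
    - cut-off
    - cutoff
  # A number directly followed by one of these is a measurement with
  # units (pharmacokinetic AUCs and the like), never an AUC fraction.
  unit_suffixes:
    - ng
    - "µg"
    - ug
    - mg
    - g
    - kg
    - mol
    - mmol
    - nmol
    - "µmol"
    - umol
    - h
    - hr
    - hrs
    - min
    - ml
    - dl
    - l
  # Maximum distance (characters) between a cue and a number it claims.
  association_window: 250
  # Sentences matching any of these (case-insensitive regex) near an AUC
  # cue define the AUC scale rather than report a result.
  scale_definition_patterns:
    - 'ranges?\s+(?:from|between)'
    - 'values?\s+(?:between|from|of|over|above|under|greater)\b[^.;]*\bconsidered'
    - 'considered\s+(?:excellent|outstanding|good|acceptable|fair|poor|failed)'
    - '\binterpreted\s+as\b'
exclusions:
  # Abstracts with this many words or fewer are excluded.
  max_short_words: 10
  # MeSH headings (substring, case-insensitive) flagging pharmacokinetic
  # studies, whose area-under-curve statistics are dosage measures.
  pharmacokinetic_mesh:
    - pharmacokinetic
    - biological availability
    - metabolic clearance rate
    - area under curve/blood
    - therapeutic equivalency
    - drug monitoring
  pharmacokinetic_pubtypes: []
  meta_analysis_pubtypes:
    - meta-analysis
  meta_analysis_title_keywords:
    - meta-analysis
    - meta analysis
    - metaanalysis
    - pooled analysis
  tutorial_pubtypes: []
  tutorial_title_keywords:
    - tutorial
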