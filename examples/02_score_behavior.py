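"""Fluency scoring, demographic z-adjustment and dichotomization.

Semantic fluency = animals named in 2 min; phonemic fluency = correct,
non-repeated words over the two 1-min letter trials (N + A).  Raw counts
are standardized to z scores after regressing out age, sex and education,
and flagged as impaired when the raw score falls strictly below the
normative 5th-percentile cutoff.
"""

from fluencymap import SEMANTIC, PHONEMIC, adjust_for_demographics, make_cohort
from fluencymap.behavior import dichotomize_series, fluency_scores, score_fluency_trial
from fluencymap.synthetic import default_norms

# trial-level scoring: repetitions count once, case-insensitive
words = ["ape", "bear", "Ape", "cat", "bear ", "dog"]
print(f"trial {words} -> {score_fluency_trial(words)} correct non-repeated words")

cohort = make_cohort(seed=1)
frame = fluency_scores(cohort.behavior_frame())
print(f"\nsemantic raw: mean {frame[SEMANTIC].mean():.1f}, sd {frame[SEMANTIC].std():.1f}")
print(f"phonemic raw: mean {frame[PHONEMIC].mean():.1f}, sd {frame[PHONEMIC].std():.1f}")

res = adjust_for_demographics(
    frame[SEMANTIC], frame["age"], frame["sex"], frame["education"], test=SEMANTIC
)
print(f"\nadjustment coefficients: { {k: round(v, 3) for k, v in res.coefficients.items()} }")
print(f"z mean {res.z.mean():.2e} (0 by construction), residual sd {res.residual_sd:.2f}")

flags = dichotomize_series(frame[SEMANTIC], default_norms(), SEMANTIC)
print(f"\nimpaired semantic fluency: {int(flags.sum())} of {cohort.n_subjects} "
      f"(below the normative cutoff {default_norms().cutoff(SEMANTIC):.0f})")
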