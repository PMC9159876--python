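"""Score a Short-Form McGill Pain Questionnaire-2 response.

22 pain-quality items, each rated 0-10, summed into four subclasses
(continuous, intermittent, neuropathic, affective) and a 0-220 total.
"""

from painmap import ITEM_NAMES, score_sfmpq2, validate_patient

ratings = {name: 0 for name in ITEM_NAMES}
ratings.update({
    "heavy": 6, "aching": 4, "throbbing": 3,   # continuous qualities
    "shooting": 2, "splitting": 1,             # intermittent
    "light_touch": 3, "numbness": 5,           # neuropathic
    "tiring_exhausting": 4,                    # affective
})
# long-form column headers fold onto the same canonical item names:
assert score_sfmpq2(
    {("Pain caused by light touch" if k == "light_touch" else k): v
     for k, v in ratings.items()}
).neuropathic_pain == 8

scores = score_sfmpq2(ratings)
print("continuous :", scores.continuous_pain)
print("intermittent:", scores.intermittent_pain)
print("neuropathic :", scores.neuropathic_pain)
print("affective   :", scores.affective)
print("total       :", scores.total, "(of 220)")

assessment = validate_patient(pain_site_cm=12.5, nrs=5, items=ratings)
print(f"\npatient accepted: NRS {assessment.nrs}, "
      f"pain site {assessment.pain_site_cm} cm from sheet top")
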