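# Scoring definition for the 16-item Diabetes Self-Management Questionnaire.
#
# Items are answered 0 ("does not apply to me") to 3 ("applies to me very
# much").  Negatively worded items are reverse coded (r -> 3 - r) before
# scoring so that higher always means more self-management.  Each subscale
# is transformed to 0-10 as sum / (3 * n_answered) * 10; the composite is
# the mean of the four subscale scores.
#
# Subscale membership and reverse flags follow the instrument's published
# scoring key: 15 items load on the four subscales, item 16 is a general
# self-care appraisal used only in the full-scale sum, and 9 items are
# reverse coded.  Override with your own YAML of the same shape if your
# instrument version differs.
name: DSMQ
n_items: 16
response_min: 0
response_max: 3
subscales:
  glucose_management: [1, 4, 6, 10, 12]
  dietary_control: [2, 5, 9, 13]
  physical_activity: [8, 11, 15]
  health_care_use: [3, 7, 14]
reverse_items: [5, 7, 10, 11, 12, 13, 14, 15, 16]
min_answered_fraction: 0.5
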