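"""Reference summary statistics of the manually cleaned 2015-16 department
cohort, used as verification inputs.

``REFERENCE_GROUP_PATIENTS`` lists the largest 20 diagnosis-intent groups of
the manually cleaned dataset with their patient counts; the remaining groups
hold ``REFERENCE_OTHER_PATIENTS`` patients in total.  ``MOULD_REF_DET_PAIRS``
gives, for the same 20 groups, the mould-appointment counts in the manually
cleaned (reference) and automatically cleaned (tool) datasets.
"""

REFERENCE_GROUP_PATIENTS = [
    (("C50", "curative"), 716),
    (("C77-79", "palliative"), 515),
    (("C61", "curative"), 345),
    (("C34", "curative"), 204),
    (("C34", "palliative"), 162),
    (("C71", "palliative"), 68),
    (("C61", "palliative"), 56),
    (("C54", "curative"), 56),
    (("C09", "curative"), 49),
    (("C20", "curative"), 49),
    (("C77", "curative"), 48),
    (("C15", "curative"), 44),
    (("C53", "curative"), 44),
    (("C50", "palliative"), 41),
    (("C90", "palliative"), 40),
    (("C01", "curative"), 38),
    (("C21", "curative"), 35),
    (("C83", "curative"), 32),
    (("C44", "curative"), 31),
    (("C49", "curative"), 26),
]

REFERENCE_OTHER_PATIENTS = 610
REFERENCE_TOTAL_PATIENTS = 3209

#: (reference, tool) mould appointment counts for the 20 groups above,
#: in the reference ranking order.
MOULD_REF_DET_PAIRS = [
    (45, 47),
    (305, 308),
    (1, 1),
    (109, 118),
    (128, 136),
    (68, 65),
    (24, 27),
    (11, 12),
    (50, 56),
    (1, 1),
    (20, 20),
    (42, 47),
    (3, 4),
    (18, 26),
    (20, 21),
    (40, 38),
    (4, 4),
    (34, 31),
    (31, 30),
    (26, 19),
]
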