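"""The two published optimal staging strategies, built by hand.

Under the effectiveness-only criterion: a positive CT scan is followed by
TBNA and the combined EBUS+EUS session; a negative CT scan by PET and
EBUS+EUS. When the needle/PET test was positive, mediastinoscopy is done
only if EBUS and EUS are both negative; when it was negative, only if EBUS
and EUS contradict each other. Chemoradiotherapy follows a positive final
test, thoracotomy a negative one.

Under net health benefit at 30,000 EUR/QALY: a positive CT scan is followed
by TBNA; EBUS alone is done only when the CT scan or the TBNA is negative;
PET and mediastinoscopy are never performed; chemoradiotherapy follows a
positive last test and thoracotomy a negative one.
"""

from mediastage.strategy import Action, Observation

CHEMO = "chemoradiotherapy"
THOR = "thoracotomy"


def leaf(option):
    return Action("Treatment", option, None)


def no_med(option):
    return Action("Dec_MED", "no", leaf(option))


def med_branch():
    """Mediastinoscopy decides the treatment: positive -> chemoradiotherapy,
    negative -> thoracotomy."""
    return Action("Dec_MED", "yes", Observation(("MED",), (
        ((("positive",),), leaf(CHEMO)),
        ((("negative",),), leaf(THOR)),
    )))


def ebus_eus_block(prior_test_positive):
    """The joint EBUS+EUS observation after a performed needle/PET test."""
    if prior_test_positive:
        branches = (
            ((("negative", "negative"),), med_branch()),
            ((("positive", "positive"),), no_med(CHEMO)),
            ((("positive", "negative"),), no_med(CHEMO)),
            ((("negative", "positive"),), no_med(CHEMO)),
        )
    else:
        branches = (
            ((("negative", "negative"),), no_med(THOR)),
            ((("positive", "positive"),), no_med(CHEMO)),
            ((("positive", "negative"),), med_branch()),
            ((("negative", "positive"),), med_branch()),
        )
    return Action("Dec_EBUS_EUS", "ebus_eus", Observation(("EBUS", "EUS"), branches))


def effectiveness_tree():
    ct_pos = Action("Dec_TBNA", "yes", Observation(("TBNA",), (
        ((("positive",),), Action("Dec_PET", "no", ebus_eus_block(True))),
        ((("negative",),), Action("Dec_PET", "no", ebus_eus_block(False))),
    )))
    ct_neg = Action("Dec_TBNA", "no", Action("Dec_PET", "yes", Observation(("PET",), (
        ((("positive",),), ebus_eus_block(True)),
        ((("negative",),), ebus_eus_block(False)),
    ))))
    return Observation(("CT_scan",), (
        ((("positive",),), ct_pos),
        ((("negative",),), ct_neg),
    ))


def ebus_alone():
    """EBUS alone decides the treatment; no mediastinoscopy afterwards."""
    return Action("Dec_EBUS_EUS", "ebus", Observation(("EBUS",), (
        ((("positive",),), no_med(CHEMO)),
        ((("negative",),), no_med(THOR)),
    )))


def nhb_tree():
    ct_pos = Action("Dec_TBNA", "yes", Observation(("TBNA",), (
        ((("positive",),), Action("Dec_PET", "no",
                                  Action("Dec_EBUS_EUS", "no_test", no_med(CHEMO)))),
        ((("negative",),), Action("Dec_PET", "no", ebus_alone())),
    )))
    ct_neg = Action("Dec_TBNA", "no", Action("Dec_PET", "no", ebus_alone()))
    return Observation(("CT_scan",), (
        ((("positive",),), ct_pos),
        ((("negative",),), ct_neg),
    ))
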