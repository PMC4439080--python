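"""Shared synthetic-panel fixture construction for pipeline-level tests."""

from paleocattle.haplogroups import default_ruleset
from paleocattle.seqio import DLOOP_REGION, ND5_REGION, Q_FRAGMENT_REGION
from paleocattle.synthdata import CohortSpec, PanelPlan, simulate_panel

#: the three-fragment marker design (181 + 77 + 486 = 744 columns); covers
#: every shipped diagnostic position including the Q split at 15953
PANEL_REGION = (ND5_REGION, Q_FRAGMENT_REGION, DLOOP_REGION)

PLAN = PanelPlan(
    cohorts=(
        CohortSpec("Prehistoric", "Finland", 5, {"T3": 0.6, "T3b": 0.2, "T1f": 0.2},
                   y1_freq=0.1, male_frac=0.4),
        CohortSpec("Medieval", "Finland", 8, {"T3": 0.5, "T3b": 0.3, "T2": 0.2},
                   y1_freq=0.1, male_frac=0.4),
        CohortSpec("Post-Medieval", "Estonia", 10, {"T3": 0.5, "T3b": 0.25, "Q": 0.25},
                   y1_freq=0.5, male_frac=0.4),
        CohortSpec("Modern", "Finland", 12, {"T3": 0.7, "T3b": 0.3},
                   y1_freq=0.9, male_frac=0.4),
    ),
    private_rate=0.004,
)


def make_panel_inputs(seed: int):
    return simulate_panel(PLAN, default_ruleset(), PANEL_REGION, seed=seed)
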