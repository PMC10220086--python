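"""Model-free proactive control: trial history labels, post-error slowing,
post-error stop-accuracy effect, and the cue-context effect.

History labels classify each trial by its immediate predecessor within the
same run: GoPUS is a go-class trial after an unsuccessful stop (the subject
responded despite the stop signal), GoPSG a go-class trial after a correct
responded go; StopPUS/StopPSG analogously for stop trials.  Post-error
slowing is the GoPUS - GoPSG difference in mean RT; the stop-accuracy
effect is the StopPUS - StopPSG difference in withhold rate.  Context
effect (CSST only) is mean uncertain-go RT minus mean certain-go RT.
"""

from __future__ import annotations

import pandas as pd

GO_CLASS = ("go", "certain_go", "uncertain_go")
LABELS = ("GoPUS", "GoPSG", "StopPUS", "StopPSG", "other")


def label_history(trials: pd.DataFrame) -> pd.Series:
    """Assign one history label per trial.

    Labels never cross run boundaries; the first trial of each run is
    'other'.  The predecessor defines the label: an unsuccessful stop
    (responded stop trial) yields *PUS, a successful go (responded and
    correct go-class trial) yields *PSG; any other predecessor yields
    'other'.
    """
    labels = pd.Series("other", index=trials.index, name="history_label", dtype=object)
    for (_, _), run_df in trials.groupby(["task", "run"], sort=False):
        run_df = run_df.sort_values("trial_index")
        if not run_df["trial_index"].is_monotonic_increasing:
            raise ValueError("trials must be ordered by trial_index within run")
        idx = run_df.index.to_numpy()
        ttype = run_df["trial_type"].to_numpy()
        responded = run_df["responded"].to_numpy(bool)
        correct = run_df["choice_correct"].fillna(False).to_numpy(bool)
        for i in range(1, len(idx)):
            prev_unsucc_stop = ttype[i - 1] == "stop" and responded[i - 1]
            prev_succ_go = ttype[i - 1] in GO_CLASS and responded[i - 1] and correct[i - 1]
            cur_go = ttype[i] in GO_CLASS
            if prev_unsucc_stop:
                labels.loc[idx[i]] = "GoPUS" if cur_go else "StopPUS"
            elif prev_succ_go:
                labels.loc[idx[i]] = "GoPSG" if cur_go else "StopPSG"
    return labels


def post_error_slowing(
    trials: pd.DataFrame,
    labels: pd.Series | None = None,
    min_per_class: int = 3,
) -> tuple[float, bool]:
    """Mean RT(responded GoPUS) - mean RT(responded GoPSG), in ms.

    Returns (pes, flagged); flagged (with NaN value) when either class has
    fewer than ``min_per_class`` responded trials.
    """
    if labels is None:
        labels = label_history(trials)
    pus = trials[(labels == "GoPUS") & trials["responded"]]["rt"].to_numpy(float)
    psg = trials[(labels == "GoPSG") & trials["responded"]]["rt"].to_numpy(float)
    if len(pus) < min_per_class or len(psg) < min_per_class:
        return float("nan"), True
    return float(pus.mean() - psg.mean()), False


def post_error_stop_accuracy_effect(
    trials: pd.DataFrame,
    labels: pd.Series | None = None,
    min_per_class: int = 2,
) -> tuple[float, bool]:
    """Withhold rate(StopPUS) - withhold rate(StopPSG).

    Returns (effect, flagged); flagged when either class has fewer than
    ``min_per_class`` trials.
    """
    if labels is None:
        labels = label_history(trials)
    pus = trials[labels == "StopPUS"]
    psg = trials[labels == "StopPSG"]
    if len(pus) < min_per_class or len(psg) < min_per_class:
        return float("nan"), True
    rate_pus = float((~pus["responded"]).mean())
    rate_psg = float((~psg["responded"]).mean())
    return rate_pus - rate_psg, False


def context_effect(trials: pd.DataFrame, min_per_class: int = 5) -> tuple[float, bool]:
    """Cue-context slowing on the CSST: mean uncertain-go RT minus mean
    certain-go RT over responded trials.

    Returns (effect in ms, flagged); flagged when either cue class has fewer
    than ``min_per_class`` responded trials.
    """
    if not (trials["task"] == "CSST").all():
        raise ValueError("context effect is defined for CSST trials only")
    unc = trials[(trials["trial_type"] == "uncertain_go") & trials["responded"]]
    cer = trials[(trials["trial_type"] == "certain_go") & trials["responded"]]
    if len(unc) < min_per_class or len(cer) < min_per_class:
        return float("nan"), True
    return float(unc["rt"].mean() - cer["rt"].mean()), False
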