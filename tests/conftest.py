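import numpy as np
import pandas as pd
import pytest

from affectdyn import (
    GroupDesign,
    build_lagged,
    extract_outcome,
    simulate_study,
)


def three_group_config(n_per_group=15, n_days=2, prompts_per_day=11, compliance=1.0,
                       lv_spread=0.1):
    """Illustrative 3-group generative truth (not estimates of any real population)."""
    return {
        "outcome": "distress",
        "seed": 0,
        "population": {
            "reference_group": "BPD",
            "reference_means": [5.0, 0.3, 0.0],
            "between_person_cov": [
                [0.5, 0.0, 0.0],
                [0.0, 0.02, 0.0],
                [0.0, 0.0, lv_spread],
            ],
            "group_deltas": {"PD": [-2.0, -0.1, 0.3], "MD": [-1.3, 0.05, 0.1]},
            "allow_degenerate": lv_spread == 0,
        },
        "design": {
            "n_days": n_days,
            "prompts_per_day": prompts_per_day,
            "scale_min": 0,
            "scale_max": 9,
            "compliance": compliance,
        },
        "group_sizes": {"BPD": n_per_group, "PD": n_per_group, "MD": n_per_group},
    }


@pytest.fixture(scope="session")
def small_study():
    """Simulated 3-group study with its analysis-ready lagged frame."""
    cfg = three_group_config(n_per_group=12, prompts_per_day=11)
    frame = simulate_study(cfg, seed=42)
    lagged = build_lagged(extract_outcome(frame, "distress"))
    design = GroupDesign.from_labels(lagged["group"], "BPD")
    return cfg, frame, lagged, design


@pytest.fixture()
def tiny_lagged():
    """Hand-sized analysis frame: 2 persons x 4 usable rows, 2 groups."""
    rng = np.random.default_rng(5)
    rows = []
    for pid, group in [("p1", "A"), ("p2", "B")]:
        y = rng.normal(size=5)
        x = y[:-1] - y[:-1].mean()
        for t in range(4):
            rows.append({"person_id": pid, "group": group, "day": 0,
                         "prompt_index": t + 1, "y": y[t + 1], "x_lag_centered": x[t]})
    return pd.DataFrame(rows)
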