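import numpy as np
import pytest

import gapekin as g


@pytest.fixture(scope="session")
def ed28_rate_matrix() -> g.RateMatrix:
    return g.calibrate_rate_matrix(g.ed28_mean_dwells(), g.ed28_occupancies())


@pytest.fixture(scope="session")
def small_cohort():
    """60 simulated molecules at the calibrated kinetics, ground truth kept."""
    cfg = g.paper_calibrated_config(n_molecules=60, duration=3000.0, seed=11)
    return g.simulate_cohort(cfg)


def true_frame_labels(path: g.StatePath, state_fret: dict, frame_period: float,
                      n_frames: int) -> np.ndarray:
    """Ground-truth per-frame state labels: nearest state to the exact
    time-weighted frame efficiency (frames on a transition go to the
    closer state)."""
    ef = path.frame_fret(state_fret, frame_period, n_frames)
    names = np.array(sorted(state_fret, key=state_fret.__getitem__, reverse=True),
                     dtype=object)
    means = np.array([state_fret[s] for s in names])
    return names[np.argmin(np.abs(ef[:, None] - means[None, :]), axis=1)]


def path_to_dwells(path: g.StatePath, molecule_id: str = "m") -> list[g.DwellRecord]:
    """Ground-truth dwell records straight from a latent state path."""
    n = len(path.states)
    return [
        g.DwellRecord(
            molecule_id=molecule_id,
            state=s,
            start_s=float(a),
            duration_s=float(b - a),
            left_censored=(i == 0),
            right_censored=(i == n - 1),
        )
        for i, (s, a, b) in enumerate(zip(path.states, path.entry, path.exit))
    ]
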