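import numpy as np
import pytest

import lidscope as ls


@pytest.fixture(scope="session")
def four_state_session():
    """300 s semi-Markov session over four well-separated states."""
    states = ls.well_separated_states()
    imu, pose, ann, truth = ls.generate_behavior_session(states, duration=300, seed=11)
    feats = ls.session_features(imu, pose)
    return {"states": states, "imu": imu, "pose": pose, "annotations": ann,
            "truth": truth, "features": feats}


@pytest.fixture(scope="session")
def segmented_four_state(four_state_session):
    feats = four_state_session["features"]
    cps, segs, symbols = ls.segment_session(feats)
    return {**four_state_session, "change_points": cps, "segments": segs,
            "symbols": symbols}


@pytest.fixture(scope="session")
def clustered_four_state(segmented_four_state):
    segs = segmented_four_state["segments"]
    library, est = ls.cluster_segments(segs, random_state=0)
    truth = segmented_four_state["truth"]

    def majority(seg):
        span = truth.state_per_sample[seg.start_idx : seg.end_idx]
        vals, cnt = np.unique(span, return_counts=True)
        return int(vals[np.argmax(cnt)])

    y_true = np.array([majority(s) for s in segs])
    return {**segmented_four_state, "library": library, "estimator": est,
            "y_true": y_true}


@pytest.fixture(scope="session")
def tuned_setup():
    """200 neurons at 20 fps, 20% tuned (3x rate) to state 2 of four states."""
    fps = 20.0
    states = ls.well_separated_states()
    _, _, _, truth = ls.generate_behavior_session(states, duration=300, seed=5)
    n_neurons = 200
    mult = np.ones((n_neurons, 4))
    tuned = np.arange(40)
    mult[tuned, 2] = 3.0
    _, ctruth = ls.generate_calcium(
        truth, n_neurons=n_neurons, baseline_rate=0.15, multipliers=mult, seed=6
    )
    frame_times = np.arange(int(300 * fps)) / fps
    imu_idx = np.minimum(
        (frame_times * truth.rate).astype(int), truth.state_per_sample.size - 1
    )
    occ = (truth.state_per_sample[imu_idx] == 2).astype(float)
    return ctruth, occ, tuned


@pytest.fixture(scope="session")
def dyskinetic_session():
    """120 s session from the dyskinetic repertoire with annotations."""
    states = ls.dyskinetic_states()
    imu, pose, ann, truth = ls.generate_behavior_session(states, duration=120, seed=21)
    feats = ls.session_features(imu, pose)
    return {"states": states, "imu": imu, "pose": pose, "annotations": ann,
            "truth": truth, "features": feats}
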