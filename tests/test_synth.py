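import numpy as np
import pytest

from asfemg.synth import (
    GestureTemplate,
    SubjectProfile,
    default_templates,
    generate_cohort,
    generate_recording,
)


def _profile(**kw):
    defaults = dict(subject_id="s", rng_seed=5, failed_burst_prob_paretic=0.0)
    defaults.update(kw)
    return SubjectProfile(**defaults)


def test_template_invariants_enforced():
    with pytest.raises(ValueError):
        GestureTemplate("rest", (0.3, 0.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        GestureTemplate("fist", (0.4, 0.3, 0.1, 0.1))
    with pytest.raises(ValueError):
        GestureTemplate("fist", (0.9, 0.1, 0.1, 0.1), carrier_band_hz=(10, 200))


def test_reps_precondition():
    with pytest.raises(ValueError, match="reps"):
        generate_recording(_profile(), "non-paretic", reps=2)


def test_dropout_free_burst_count_and_block_structure():
    rec = generate_recording(_profile(), "non-paretic", reps=10)
    truth = rec.meta["truth"]
    per_gesture = {}
    for b in truth["bursts"]:
        per_gesture.setdefault(b["gesture"], []).append(b)
    assert set(per_gesture) == {t.gesture_id for t in default_templates()} - {"rest"}
    for bursts in per_gesture.values():
        assert len(bursts) == 10
        assert not any(b["dropped"] for b in bursts)


def test_seeded_determinism_byte_identical():
    a = generate_recording(_profile(), "paretic", reps=4)
    b = generate_recording(_profile(), "paretic", reps=4)
    assert np.array_equal(a.mv, b.mv)


def test_sides_differ_but_share_subject_seed():
    a = generate_recording(_profile(), "paretic", reps=4)
    b = generate_recording(_profile(), "non-paretic", reps=4)
    assert not np.array_equal(a.mv, b.mv)


def test_amplitude_bounded_by_device_range():
    rec = generate_recording(_profile(rng_seed=3), "non-paretic", reps=10)
    assert np.abs(rec.mv).max() <= 1.5


def _burst_rms(rec, gesture, channel):
    fs = rec.fs_hz
    vals = []
    for b in rec.meta["truth"]["bursts"]:
        if b["gesture"] != gesture or b["dropped"]:
            continue
        i0, i1 = int(b["t_on"] * fs), int(b["t_off"] * fs)
        vals.append(np.sqrt(np.mean(rec.mv[channel, i0:i1] ** 2)))
    return np.mean(vals)


def test_paretic_amplitude_scale_halves_burst_rms():
    prof = _profile(
        amplitude_scale_paretic=0.5,
        crosstalk_paretic=0.0,
        snr_db_nonparetic=30.0,
        snr_db_paretic=30.0,
    )
    rp = generate_recording(prof, "paretic", reps=10)
    rn = generate_recording(prof, "non-paretic", reps=10)
    ratio = _burst_rms(rp, "wrist_flexion", 0) / _burst_rms(rn, "wrist_flexion", 0)
    assert ratio == pytest.approx(0.5, rel=0.10)


def test_dominant_channel_exceeds_rest_envelope_by_6db():
    rec = generate_recording(_profile(), "non-paretic", reps=6)
    fs = rec.fs_hz
    idle = rec.meta["truth"]["idle"][0]
    for tpl in default_templates():
        if tpl.gesture_id == "rest":
            continue
        dom = int(np.argmax(tpl.activation))
        burst = _burst_rms(rec, tpl.gesture_id, dom)
        i0, i1 = int((idle["t_start"] + 0.2) * fs), int((idle["t_end"] - 0.2) * fs)
        rest = np.sqrt(np.mean(rec.mv[dom, i0:i1] ** 2))
        assert 20 * np.log10(burst / rest) >= 6.0


def test_failed_bursts_reduce_active_count():
    prof = _profile(failed_burst_prob_paretic=0.3, rng_seed=21)
    rec = generate_recording(prof, "paretic", reps=10)
    dropped = [b for b in rec.meta["truth"]["bursts"] if b["dropped"]]
    assert dropped, "expected some failed bursts at p=0.3"


def test_cohort_reproducible_and_validated():
    with pytest.raises(ValueError):
        generate_cohort(3, seed=1)
    a = generate_cohort(4, seed=9, reps=3)
    b = generate_cohort(4, seed=9, reps=3)
    assert len(a) == 4
    for (pa, rpa, rna), (pb, rpb, rnb) in zip(a, b):
        assert pa == pb
        assert np.array_equal(rpa.mv, rpb.mv)
        assert np.array_equal(rna.mv, rnb.mv)
    c = generate_cohort(4, seed=10, reps=3)
    assert a[0][0] != c[0][0]


def test_profile_invariants():
    with pytest.raises(ValueError):
        SubjectProfile(subject_id="x", snr_db_nonparetic=10, snr_db_paretic=12)
    with pytest.raises(ValueError):
        SubjectProfile(subject_id="x", crosstalk_paretic=0.7)
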