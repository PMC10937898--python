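"""Error-channel simulation and recovery accounting."""

import numpy as np
import pytest

from drrc import pipeline
from drrc.channel import (
    ErrorSpec,
    evaluate_recovery,
    inject_errors,
    make_fixture,
    run_experiment,
)


def test_fixture_reproducible_and_sized():
    a = make_fixture(1024, seed=7)
    b = make_fixture(1024, seed=7)
    c = make_fixture(1024, seed=8)
    assert a == b and a != c and len(a) == 1024
    with pytest.raises(ValueError):
        make_fixture(0, seed=1)


def test_fixture_size_matches_reference_segmenting():
    from drrc.bitstream import segment_message
    segs, _ = segment_message(make_fixture(876960, seed=1))
    assert len(segs) == 25056


def test_error_spec_validation():
    with pytest.raises(ValueError):
        ErrorSpec(rate=1.5)
    with pytest.raises(ValueError):
        ErrorSpec(rate=0.1, mix=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        ErrorSpec(rate=0.1, convention="per_oligo")
    mix = ErrorSpec.mix_from_ratio(27, 1)
    assert mix[0] == pytest.approx(27 / 28)
    assert mix[1] == mix[2] == pytest.approx(1 / 56)


@pytest.fixture(scope="module")
def small_pool():
    data = make_fixture(35 * 40, seed=5)
    enc = pipeline.encode_bytes(data)
    return enc, [o.full for o in enc.oligos]


def test_zero_rate_is_identity(small_pool):
    _, pool = small_pool
    assert inject_errors(pool, ErrorSpec(rate=0.0, seed=1)) == pool


def test_substitutions_preserve_length(small_pool):
    _, pool = small_pool
    out = inject_errors(pool, ErrorSpec(rate=1.0, mix=(1, 0, 0), seed=2))
    assert [len(s) for s in out] == [len(s) for s in pool]
    assert sum(a != b for a, b in zip(out, pool)) == len(pool)


def test_indels_shift_length_by_one(small_pool):
    _, pool = small_pool
    out = inject_errors(pool, ErrorSpec(rate=1.0, mix=(0, 0.5, 0.5), seed=3))
    assert all(abs(len(a) - len(b)) == 1 for a, b in zip(out, pool))


def test_core_only_leaves_primers_intact(small_pool):
    _, pool = small_pool
    out = inject_errors(pool, ErrorSpec(rate=1.0, seed=4, region="core-only"))
    for s in out:
        assert s[:24] == pool[0][:24]
        assert s[-24:] == pool[0][-24:]


def test_per_sequence_corruption_count_binomial(small_pool):
    """~rate fraction of oligos touched; mean over seeds near expectation."""
    _, pool = small_pool
    rate, n = 0.25, len(pool)
    counts = []
    for seed in range(30):
        out = inject_errors(pool, ErrorSpec(rate=rate, seed=seed))
        counts.append(sum(a != b for a, b in zip(out, pool)))
    mean = np.mean(counts)
    sd = np.sqrt(n * rate * (1 - rate) / 30)
    assert abs(mean - n * rate) < 4 * sd + 1


def test_evaluate_recovery_counting(rng):
    original = rng.integers(0, 2, (10, 280)).astype(np.uint8)
    decoded = {k: original[k].copy() for k in range(9)}
    rep = evaluate_recovery(original, decoded)
    assert (rep.n_total, rep.n_recovered, rep.rate) == (10, 9, 0.9)
    assert evaluate_recovery(original, {}).rate == 0.0
    full = {k: original[k] for k in range(10)}
    assert evaluate_recovery(original, full).rate == 1.0
    wrong = {k: 1 - original[k] for k in range(10)}
    assert evaluate_recovery(original, wrong).rate == 0.0


def test_experiment_reproducible_and_dominant():
    kw = dict(n_oligos=60, rates=(0.05, 0.2), replicates=3, seed=9,
              error_type="mixed")
    df1 = run_experiment(**kw)
    df2 = run_experiment(**kw)
    assert df1.equals(df2)
    # paired correction dominance: resync+rs >= resync >= none per cell
    wide = df1.pivot_table(index=["rate", "replicate"], columns="correction",
                           values="recovery_rate")
    assert (wide["resync+rs"] >= wide["resync"] - 1e-12).all()
    assert (wide["resync"] >= wide["none"] - 1e-12).all()


def test_experiment_recovery_monotone_in_rate():
    df = run_experiment(n_oligos=150, rates=(0.01, 0.3, 0.8), replicates=4,
                        seed=2, error_type="substitution",
                        corrections=("none",))
    means = df.groupby("rate")["recovery_rate"].mean()
    assert means.is_monotonic_decreasing
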