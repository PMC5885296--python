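import numpy as np
import pytest

import sulston as s


@pytest.fixture(scope="session")
def embryo():
    """Canonically oriented synthetic embryo, 3 division rounds, no noise."""
    return s.generate(s.SimConfig(seed=11, n_rounds=3))


@pytest.fixture(scope="session")
def rotated_embryo():
    orientation = s.random_orientation(np.random.default_rng(17), translation_um=25.0)
    return s.generate(s.SimConfig(seed=11, n_rounds=3, orientation=orientation))


def name_embryo(result, rules=None, seeds=None):
    """Run the full naming pipeline on a generator result."""
    tree = s.build_tracks(result.frames)
    transform = s.canonical_transform(
        result.metadata.ap_vector, result.metadata.lr_vector
    )
    if seeds is None:
        seeds = s.seed_founders(tree, transform, result.metadata)
    if rules is None:
        rules = s.NamingRuleSet(expected_axes=result.expected_axes)
    assignments = s.assign_names(
        tree, transform, rules, result.metadata, seeds=seeds
    )
    return tree, transform, rules, seeds, assignments


def random_forest_frames(rng, n_frames=6, n_roots=4, p_divide=0.25, p_lose=0.1,
                         max_new_roots=2):
    """Random link-consistent per-frame records for structural tests."""
    frames = [[] for _ in range(n_frames)]

    def new_record(t):
        rec = s.NucleusRecord(
            time=t, index=len(frames[t - 1]) + 1,
            x=float(rng.uniform(0, 100)), y=float(rng.uniform(0, 100)),
            z=float(rng.uniform(0, 20)), diameter=20.0, weight=1000.0,
        )
        frames[t - 1].append(rec)
        return rec

    open_records = [new_record(1) for _ in range(n_roots)]
    for t in range(2, n_frames + 1):
        next_open = []
        for rec in open_records:
            u = rng.random()
            if u < p_lose:
                continue
            if u < p_lose + p_divide:
                d1, d2 = new_record(t), new_record(t)
                rec.successor1, rec.successor2 = d1.index, d2.index
                d1.predecessor = d2.predecessor = rec.index
                next_open += [d1, d2]
            else:
                d = new_record(t)
                rec.successor1, d.predecessor = d.index, rec.index
                next_open.append(d)
        for _ in range(int(rng.integers(0, max_new_roots + 1))):
            next_open.append(new_record(t))
        open_records = next_open
    return frames
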