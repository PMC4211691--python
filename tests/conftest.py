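import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_capture_table():
    """Five individuals, survey years 2000-2003, no excluded years.

    Detection patterns chosen so the m-array can be tabulated by hand:
    A released 2000 (age 3), seen 2002; B released 2000 (age 3), seen 2001
    and 2003; C released 2000 (age 7), never seen; D released 2001 (age 3),
    seen 2002; E released 2001 (age 3), never seen.
    """
    rows = []
    spec = [
        ("A", 2000, 3, {2002}),
        ("B", 2000, 3, {2001, 2003}),
        ("C", 2000, 7, set()),
        ("D", 2001, 3, {2002}),
        ("E", 2001, 3, set()),
    ]
    for iid, ry, age, seen in spec:
        rows.append({
            "individual_id": iid, "release_year": ry, "release_site": "tunas",
            "age_at_release": age, "native_born": 0,
            **{f"y{y}": int(y in seen) for y in range(2000, 2004)},
        })
    return pd.DataFrame(rows)


def random_capture_table(rng: np.random.Generator, n_ind: int, years):
    """Random small capture table honoring the no-detection-before-release
    invariant; used by likelihood-equivalence tests."""
    years = list(years)
    rows = []
    for i in range(n_ind):
        ry = int(rng.choice(years[:-1]))
        age = int(rng.integers(2, 12))
        det = {y: 0 for y in years}
        for y in years:
            if y > ry and rng.random() < 0.5:
                det[y] = 1
        rows.append({
            "individual_id": f"i{i}", "release_year": ry,
            "release_site": "tunas", "age_at_release": age, "native_born": 0,
            **{f"y{y}": det[y] for y in years},
        })
    return pd.DataFrame(rows)
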