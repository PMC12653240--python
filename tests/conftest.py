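"""Shared fixtures: desk-scale phantom cohorts generated on the fly."""

import numpy as np
import pytest

from gliomgmt.phantom import PhantomParams, generate_cohort, generate_phantom_case


@pytest.fixture()
def desk_params():
    return PhantomParams.desk_scale(seed=7)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Six-case desk-scale phantom cohort written as NIfTI + labels CSV."""
    out = tmp_path_factory.mktemp("cohort")
    params = PhantomParams.desk_scale(seed=11)
    table = generate_cohort(6, 0.5, params, out)
    return out, table


@pytest.fixture(scope="session")
def phantom_case_pair():
    """One methylated and one unmethylated case from the same geometry."""
    params = PhantomParams.desk_scale(seed=3)
    return (generate_phantom_case(params, 0, "00000"),
            generate_phantom_case(PhantomParams.desk_scale(seed=4), 1, "00001"))


def flood_fill_largest(mask: np.ndarray) -> int:
    """Recursive flood-fill oracle: largest 8-connected component area."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    best = 0
    for si in range(h):
        for sj in range(w):
            if not mask[si, sj] or seen[si, sj]:
                continue
            area, stack = 0, [(si, sj)]
            seen[si, sj] = True
            while stack:
                i, j = stack.pop()
                area += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (0 <= ni < h and 0 <= nj < w
                                and mask[ni, nj] and not seen[ni, nj]):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
            best = max(best, area)
    return best


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Exhaustive 256-threshold search maximizing between-class variance."""
    vals = pixels.ravel().astype(float)
    best_t, best_s = 0, -np.inf
    for t in range(256):
        lo, hi = vals[vals <= t], vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s:
            best_s, best_t = s, t
    if best_s == -np.inf:
        return int(vals[0])
    return best_t
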