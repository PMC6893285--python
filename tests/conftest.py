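import numpy as np
import pandas as pd
import pytest

from optonotch import synthgen


def truth_spot_table(truth: synthgen.SpotMovieTruth) -> pd.DataFrame:
    """Ground-truth spot positions per frame (ON nuclei only)."""
    rows = []
    for ti, t in enumerate(truth.frame_times):
        for j in np.nonzero(truth.onset_times <= t)[0]:
            rows.append(
                {
                    "frame": ti,
                    "x_px": truth.positions.x_px[j],
                    "y_px": truth.positions.y_px[j],
                }
            )
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])


@pytest.fixture(scope="session")
def small_spot_movie():
    """A small noise-free movie with spots switching on during acquisition."""
    params = synthgen.SpotMovieParams(
        n_nuclei_per_row=10,
        movie_start=25.0,
        movie_end=45.0,
        frame_interval=2.0,
        cv_between_spots=0.0,
        seed=1,
    )
    stack, truth = synthgen.gen_spot_movie(params)
    return params, stack, truth
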