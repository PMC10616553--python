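import numpy as np
import pandas as pd
import pytest

from phosnet import synthetic
from phosnet.design import StudyDesign, default_design, make_plex


@pytest.fixture
def one_plex_design() -> StudyDesign:
    return StudyDesign((make_plex("p1", "CL1"),))


@pytest.fixture
def three_plex_design() -> StudyDesign:
    return default_design()


@pytest.fixture
def small_prior() -> synthetic.PriorNetwork:
    return synthetic.generate_prior_network(5, 10, frac_inhibitory=0.2, seed=11)


def make_reporter_row(
    design: StudyDesign,
    intensities: dict[int, float],
    peptide: str = "pep1",
    protein: str = "P1",
    site: str = "",
    loc_prob: float = np.nan,
) -> pd.DataFrame:
    """One PSM row with explicit channel intensities (missing -> NaN)."""
    plex = design.plexes[0]
    row = {
        "plex": plex.plex_id,
        "peptide": peptide,
        "protein": protein,
        "site": site,
        "loc_prob": loc_prob,
    }
    for c in range(1, 11):
        row[f"channel_{c}"] = intensities.get(c, np.nan)
    return pd.DataFrame([row])
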