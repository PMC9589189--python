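import hypothesis
import pandas as pd
import pytest

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def tiny_plate() -> pd.DataFrame:
    """One plate: positive control Delta=300, two variants in duplicate, mock.

    var_a wells summarize to 150 (normalized 0.5); var_b duplicates normalize
    to 0.4 and 0.6 (average 0.5).
    """
    def well(wid, variant, role, basal, post):
        return {
            "plate_id": "P01", "well_id": wid, "variant_id": variant, "role": role,
            "odorant": "Z4-11Al", "conc_umolL": 30.0,
            "basal_1": basal[0], "basal_2": basal[1], "basal_3": basal[2],
            "post_1": post[0], "post_2": post[1], "post_3": post[2],
        }

    rows = [
        well("A1", "mock", "mock", (100, 100, 100), (100, 100, 100)),
        well("A2", "OR1A1", "positive", (100, 110, 90), (400, 410, 390)),
        well("B1", "var_a", "test", (100, 100, 100), (250, 250, 250)),
        well("B2", "var_a", "test", (100, 100, 100), (250, 250, 250)),
        well("C1", "var_b", "test", (100, 100, 100), (220, 220, 220)),
        well("C2", "var_b", "test", (100, 100, 100), (280, 280, 280)),
    ]
    return pd.DataFrame(rows)
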