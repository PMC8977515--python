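import numpy as np
import pytest

from graftquant.cohort import BanffScores, CohortRecord, EXCLUSION_CATEGORIES
from graftquant.synthetic import SlideSpec, render_ihc_slide


#: Screening-manifest exclusion counts: seven categories plus the enrolled
#: remainder, totalling 171 screened recipients.
SCREENING_COUNTS = {
    "recurrent_or_denovo_GN": 12,
    "BKVN": 21,
    "possible_BKVN": 5,
    "TCMR_with_BK_load": 6,
    "multiorgan_tx": 2,
    "repeat_tx": 3,
    "CNI_toxicity": 16,
    "none": 106,
}

GROUP_SIZES = {"NR": 13, "Borderline": 13, "TCMR": 60, "ABMR": 20}


def make_screening_manifest():
    """171 adult records carrying the screening exclusion categories."""
    records = []
    i = 0
    for reason, count in SCREENING_COUNTS.items():
        for _ in range(count):
            i += 1
            records.append(CohortRecord(
                recipient_id=f"S{i:03d}",
                ddcfdna_fraction=1.0,
                diagnosis="TCMR" if reason == "none" else None,
                age_years=40.0,
                exclusion_reason=reason,
            ))
    return records


@pytest.fixture(scope="session")
def screening_manifest():
    return make_screening_manifest()


@pytest.fixture(scope="session")
def default_slide():
    """One rendered slide with its ground truth (session-cached)."""
    return render_ihc_slide(SlideSpec(seed=42))


@pytest.fixture(scope="session")
def small_slide():
    return render_ihc_slide(SlideSpec(
        seed=7, width_px=400, height_px=400, n_tissue_fragments=1,
        n_glomeruli=2, n_positive_cells=12, n_negative_cells=12))


def table2_counts():
    """Score-level x group contingency counts for the seven scored lesions."""
    from graftquant.synthetic import BANFF_GROUP_COUNTS

    return {
        lesion: np.array([[per_group[g][lvl] for g in ("NR", "Borderline", "TCMR", "ABMR")]
                          for lvl in range(4)])
        for lesion, per_group in BANFF_GROUP_COUNTS.items()
    }
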