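import numpy as np
import pandas as pd
import pytest

import metabophen as mp

@pytest.fixture()
def tiny_cohort_files(tmp_path):
    """3 participants × 2 metabolites on disk, with an assay spec."""
    participants = pd.DataFrame({
        "participant_id": ["P1", "P2", "P3"],
        "diagnosis": ["ASD", "ASD", "TYP"],
        "age_months": [30.0, 40.0, 25.0],
        "sex": ["M", "F", "M"],
        "hemoglobin_mgdl": [10.0, 20.0, 30.0],
    })
    conc = pd.DataFrame({
        "participant_id": ["P1", "P2", "P3"],
        "lactate": [1500.0, 1600.0, 1400.0],
        "pyruvate": [70.0, 75.0, 65.0],
    })
    ppath = tmp_path / "participants.tsv"
    cpath = tmp_path / "concentrations.tsv"
    participants.to_csv(ppath, sep="\t", index=False)
    conc.to_csv(cpath, sep="\t", index=False)
    assay = mp.AssaySpec(limits={"lactate": (100.0, 10000.0), "pyruvate": (5.0, 500.0)})
    apath = tmp_path / "assay.yaml"
    assay.to_file(apath)
    return ppath, cpath, apath


@pytest.fixture(scope="session")
def default_screened():
    """One fast full-pipeline screen on the default synthetic cohort,
    shared by integration-level tests."""
    cohort = mp.generate_cohort(mp.CohortConfig(seed=11))
    records, quant, ledger = mp.preprocess_cohort(cohort.records, cohort.quant, cohort.assay)
    defs = mp.enumerate_features(quant.metabolites, mp.defaults.LOW_QUANT_METABOLITES)
    fm = mp.compute_features(quant, defs)
    labels = records["diagnosis"].to_numpy()
    strata = mp.make_strata(records)
    result = mp.screen_all(fm, labels, strata,
                           mp.ScreenParams(repeats=5, n_perm=199, seed=11))
    profile = mp.build_profiles(result.definitions, fm)
    return {
        "cohort": cohort, "records": records, "quant": quant, "ledger": ledger,
        "fm": fm, "labels": labels, "strata": strata,
        "result": result, "profile": profile,
    }


def make_profile(matrix: np.ndarray, participants=None, biomarkers=None) -> mp.BiomarkerProfile:
    """Helper to wrap a 0/1 array as a BiomarkerProfile."""
    n, b = matrix.shape
    idx = participants if participants is not None else [f"P{i}" for i in range(n)]
    cols = biomarkers if biomarkers is not None else [f"B{j}" for j in range(b)]
    return mp.BiomarkerProfile(matrix=pd.DataFrame(
        np.asarray(matrix, dtype=np.int8), index=idx, columns=cols))
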