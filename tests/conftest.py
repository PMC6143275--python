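import numpy as np
import pytest

from enuscreen import (
    Annotation,
    ScreenConfig,
    SpectrumConfig,
    build_annotation,
    filter_enu_candidates,
    load_variants,
    simulate_screen,
    write_cohort,
)


@pytest.fixture(scope="session")
def annotation_small() -> Annotation:
    return build_annotation(400, seed=11)


@pytest.fixture(scope="session")
def spectrum() -> SpectrumConfig:
    return SpectrumConfig()


@pytest.fixture(scope="session")
def artifact_cohort(annotation_small, spectrum):
    """40-mouse cohort with shared artifact calls and ground truth."""
    cfg = ScreenConfig(n_g1_mice=40, artifact_rate=30.0, seed=7)
    return simulate_screen(cfg, spectrum, annotation_small)


@pytest.fixture(scope="session")
def artifact_cohort_files(artifact_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    return write_cohort(
        artifact_cohort, d / "cohort.vcf", d / "truth.tsv", d / "annotation.tsv",
        d / "cohort.ped.tsv",
    )


@pytest.fixture(scope="session")
def artifact_records(artifact_cohort_files, annotation_small):
    return load_variants(artifact_cohort_files["vcf"], annotation=annotation_small)


@pytest.fixture(scope="session")
def artifact_candidates(artifact_records):
    return filter_enu_candidates(artifact_records, min_depth=6)


@pytest.fixture(scope="session")
def mouse_pool(annotation_small, spectrum):
    """~2,000 simulated G1 mice sharing one RNG stream: >1e5 ENU variants for
    frequency checks without per-test resimulation."""
    from enuscreen import simulate_g1_mouse

    cfg = ScreenConfig(de_novo_rate=0.0)
    rng = np.random.default_rng(2024)
    occupied: set = set()
    mice = []
    for i in range(2000):
        sex = "F" if rng.random() < 0.5 else "M"
        mice.append(
            simulate_g1_mouse(cfg, spectrum, annotation_small, sex, rng,
                              mouse_id=f"p{i}", occupied=occupied)
        )
    return mice
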