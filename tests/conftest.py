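import numpy as np
import pytest

import mibci as m

#: bipolar-capable mini montage: the three anodes and their synthetic cathodes
BIPOLAR_LABELS = ("Cz", "C4", "C3", "Cz'", "C4'", "C3'")

#: C4 and its four grid neighbours, for single-channel Laplacian analyses
C4_PATCH = ("C4", "FC4", "C2", "C6", "CP4")


@pytest.fixture(scope="session")
def montage():
    return m.default_montage()


@pytest.fixture(scope="session")
def bipolar_montage(montage):
    return m.montage_subset(montage, BIPOLAR_LABELS)


@pytest.fixture(scope="session")
def c4_montage(montage):
    return m.montage_subset(montage, C4_PATCH)


@pytest.fixture(scope="session")
def trained_session(bipolar_montage):
    """One 40-trial left/right session with post-training modulation depth."""
    protocol = m.SessionProtocol(n_trials=40)
    return m.generate_session(protocol, m.SubjectModel.trained(),
                              bipolar_montage, seed=7)


@pytest.fixture(scope="session")
def trained_streams(trained_session, bipolar_montage):
    rec, _ = trained_session
    return m.feature_stream(rec, montage=bipolar_montage)


@pytest.fixture(scope="session")
def null_session(bipolar_montage):
    """Same protocol, no MI modulation anywhere."""
    protocol = m.SessionProtocol(n_trials=40)
    return m.generate_session(protocol, m.SubjectModel(), bipolar_montage, seed=7)


@pytest.fixture(scope="session")
def calibrated(trained_streams, trained_session):
    rec, trials = trained_session
    return m.calibrate(trained_streams, trials, rate=rec.sample_rate)


def gaussian_classes(rng, n_per_class, mean_left, mean_right, sd):
    """Two labelled Gaussian clouds in feature space."""
    X = np.vstack([
        rng.normal(mean_left, sd, size=(n_per_class, 4)),
        rng.normal(mean_right, sd, size=(n_per_class, 4)),
    ])
    labels = np.array(["left_hand"] * n_per_class + ["right_hand"] * n_per_class)
    return X, labels
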