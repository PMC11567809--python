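import numpy as np
import pytest

from catrace import AcquisitionParams, SessionManifest, TraceMatrix


@pytest.fixture
def acq2hz() -> AcquisitionParams:
    return AcquisitionParams()


def make_session(
    values: np.ndarray,
    windows: list[tuple[int, int, str]] | None = None,
    frame_rate_hz: float = 2.0,
    animal_id: str = "test",
) -> tuple[TraceMatrix, SessionManifest]:
    """Build a session from raw values; default schedule = one rest block
    covering the first half and one running trial covering the second."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if windows is None:
        windows = [(0, n // 2, "rest"), (n // 2, n, "run")]
    manifest = SessionManifest(
        animal_id=animal_id, frame_rate_hz=frame_rate_hz, trial_windows=windows
    )
    ids = [f"n{i}" for i in range(values.shape[1])]
    trace = TraceMatrix.from_manifest(values, ids, manifest)
    return trace, manifest
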