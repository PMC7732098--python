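import pytest

from escapement import (ObservationRecord, AttemptRecord, build_survival_data,
                        read_event_log, fixture_path)


@pytest.fixture(scope="session")
def fixture_log():
    """The packaged deterministic reference ethogram (~200 fish, 2 videos)."""
    return read_event_log(fixture_path())


@pytest.fixture(scope="session")
def fixture_survival(fixture_log):
    obs, _, attempts = fixture_log
    return build_survival_data(obs, attempts)


def make_fish(fish_id="f1", video="V1", entry=0.0, exit=5.0,
              attempts=()):
    """Hand-built one-fish dataset: attempts as (time, success) pairs."""
    obs = ObservationRecord(fish_id, video, entry, exit)
    recs = [AttemptRecord(fish_id, video, i + 1, t, "top", "center", s)
            for i, (t, s) in enumerate(attempts)]
    return [obs], recs
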