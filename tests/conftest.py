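import numpy as np
import pytest

from entolat import SpikeDataset, StimulusProtocol, UnitMeta


@pytest.fixture
def protocol() -> StimulusProtocol:
    return StimulusProtocol()


def build_dataset(
    trains: dict[tuple[str, str, int], list[float]],
    units: list[UnitMeta] | None = None,
    protocol: StimulusProtocol | None = None,
) -> SpikeDataset:
    """Assemble a dataset from explicit spike trains, declaring any unit ids
    mentioned in the trains that are absent from `units`."""
    protocol = protocol or StimulusProtocol()
    units = list(units or [])
    declared = {u.unit_id for u in units}
    for uid, _, _ in trains:
        if uid not in declared:
            units.append(UnitMeta(uid, "dark", "left", "chick_0"))
            declared.add(uid)
    spikes = {k: np.asarray(v, dtype=float) for k, v in trains.items()}
    return SpikeDataset(protocol=protocol, units=units, spikes=spikes)


@pytest.fixture
def single_unit_factory(protocol):
    """Dataset factory with one unit and per-(condition, trial) trains."""

    def _make(trains: dict[tuple[str, int], list[float]], unit_id: str = "u0"):
        return build_dataset(
            {(unit_id, cond, tr): times for (cond, tr), times in trains.items()},
            units=[UnitMeta(unit_id, "dark", "left", "chick_0")],
            protocol=protocol,
        )

    return _make
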