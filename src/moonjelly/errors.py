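"""Exception types raised by the simulator."""


class MoonjellyError(Exception):
    """Base class for all package errors."""


class IntegrationError(MoonjellyError):
    """The membrane-potential integration produced a non-finite state.

    Carries the simulation time (ms) at which the state became invalid.
    """

    def __init__(self, time_ms: float):
        self.time_ms = time_ms
        super().__init__(f"non-finite membrane state at t = {time_ms:.4f} ms")


class RunawayActivityError(MoonjellyError):
    """A neuron spiked three or more times within one wave.

    Through-conducting nerve nets fire each neuron exactly once per wave;
    repeated firing indicates either pathological parameters or a bug, so the
    simulation aborts with a diagnostic instead of looping.
    """

    def __init__(self, neuron: int, time_ms: float):
        self.neuron = neuron
        self.time_ms = time_ms
        super().__init__(
            f"neuron {neuron} spiked >= 3 times (at t = {time_ms:.4f} ms); "
            "through-conduction forbids repetitive firing"
        )


class ProtocolError(MoonjellyError):
    """A stimulation protocol failed a precondition (e.g. no first spike)."""


class PropagationError(MoonjellyError):
    """An activation wave did not reach the required target neuron."""


class UndefinedStatisticError(MoonjellyError):
    """A network statistic is undefined for the given net (too few synapses)."""


class DegenerateGeometryError(MoonjellyError):
    """Geometric input is degenerate (zero-length connector, coincident points)."""


class ExportError(MoonjellyError):
    """Structure export failed (index out of range, inconsistent mesh)."""
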