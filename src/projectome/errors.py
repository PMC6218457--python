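"""Exception hierarchy shared across the pipeline."""


class ProjectomeError(Exception):
    """Base class for all package errors."""


class SwcError(ProjectomeError):
    """Base class for SWC parsing/validation failures."""


class MalformedLine(SwcError):
    """An SWC line has the wrong column count or a non-numeric field."""

    def __init__(self, line_no: int, line: str, reason: str = ""):
        self.line_no = line_no
        self.line = line
        super().__init__(f"malformed SWC line {line_no}: {line!r}" + (f" ({reason})" if reason else ""))


class MissingParent(SwcError):
    def __init__(self, node_id: int, parent_id: int):
        self.node_id = node_id
        self.parent_id = parent_id
        super().__init__(f"node {node_id} references missing parent {parent_id}")


class DuplicateId(SwcError):
    def __init__(self, node_id: int):
        self.node_id = node_id
        super().__init__(f"duplicate node id {node_id}")


class MultipleRoots(SwcError):
    def __init__(self, root_ids):
        self.root_ids = list(root_ids)
        super().__init__(f"multiple root nodes (parent -1): {self.root_ids}")


class NoRoot(SwcError):
    def __init__(self):
        super().__init__("morphology has no root node (no parent_id == -1)")


class CycleDetected(SwcError):
    def __init__(self, node_id: int):
        self.node_id = node_id
        super().__init__(f"cycle detected through node {node_id}")


class IoFailure(ProjectomeError):
    """Filesystem-level failure while reading or writing an artifact."""


class UnknownRegion(ProjectomeError):
    def __init__(self, region_id):
        self.region_id = region_id
        super().__init__(f"unknown region id {region_id}")


class BadFactor(ProjectomeError):
    def __init__(self, factors):
        super().__init__(f"downsampling factors must all be >= 1, got {factors}")


class EmptyAxon(ProjectomeError):
    """Morphology carries no axonal cable."""


class ZeroLength(ProjectomeError):
    """Projection strengths are undefined for a zero-length axon."""


class EmptyMatrix(ProjectomeError):
    """Profile categorization needs at least one neuron row."""


class SomaOutsideVolume(ProjectomeError):
    def __init__(self, position):
        self.position = tuple(position)
        super().__init__(f"soma at {self.position} falls outside the labeled volume")


class EmptyGroup(ProjectomeError):
    def __init__(self, label):
        super().__init__(f"group {label!r} has no members")


class DegenerateVariance(ProjectomeError):
    """Pooled variance is zero: the t statistic is infinite or undefined."""


class BoxOutOfBounds(ProjectomeError):
    def __init__(self, acronym, box):
        super().__init__(f"region box {acronym!r} {box} exceeds the atlas extent")


class OverlappingLayerSlabs(ProjectomeError):
    def __init__(self, area):
        super().__init__(f"layer slabs of area {area!r} overlap")


class UnreachableTarget(ProjectomeError):
    def __init__(self, acronym):
        super().__init__(f"no path to target region {acronym!r} at the given step length")


class ConfigError(ProjectomeError):
    """Run configuration is invalid (unknown key or out-of-range value)."""


class MissingUpstream(ProjectomeError):
    """A report was requested before the analysis tables were produced."""
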