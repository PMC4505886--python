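"""Exception hierarchy for vdomgeom."""


class VdomgeomError(Exception):
    """Base class for all vdomgeom errors."""


class StructureParseError(VdomgeomError):
    """A structure file could not be parsed."""


class ManifestError(VdomgeomError):
    """Dataset manifest is malformed or inconsistent with a structure file."""


class ExtractionError(VdomgeomError):
    """A variable-domain range yielded no usable residues."""


class SuperpositionError(VdomgeomError):
    """Rigid superposition is underdetermined or otherwise impossible."""


class ConvergenceError(VdomgeomError):
    """Iterative framework-subset derivation did not converge.

    Carries the last anchor subset and per-iteration diagnostics so a user can
    inspect why the ensemble has no common rigid core.
    """

    def __init__(self, message, last_subset=None, diagnostics=None):
        super().__init__(message)
        self.last_subset = last_subset
        self.diagnostics = diagnostics or []


class DegenerateGeometryError(VdomgeomError):
    """Geometry is degenerate (collinear anchors, identical poses, ...)."""


class AlignmentFormatError(VdomgeomError):
    """A multiple sequence alignment file is ragged or otherwise invalid."""
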