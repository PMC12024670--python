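"""Exception hierarchy shared across the package."""


class RulaError(Exception):
    """Base class for all rulakit errors."""


class InputError(RulaError, ValueError):
    """Invalid numeric input (non-finite angle, out-of-range table index)."""


class DegenerateGeometryError(RulaError):
    """Coincident points make an angle undefined."""


class OcclusionError(RulaError):
    """A keypoint required by an extraction rule is missing or low-confidence."""

    def __init__(self, keypoint: str, plane: str = "", detail: str = ""):
        self.keypoint = keypoint
        self.plane = plane
        msg = f"required keypoint {keypoint!r}"
        if plane:
            msg += f" in {plane} plane"
        msg += " is occluded or below the confidence threshold"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class SchemaError(RulaError):
    """A file does not conform to the expected schema."""


class ConfigError(RulaError):
    """Invalid configuration."""


class UndefinedKappaError(RulaError):
    """Chance agreement equals 1, so kappa is undefined (degenerate marginals)."""
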