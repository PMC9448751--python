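"""Exception types shared across the pipeline.

All inherit from :class:`ValueError` so callers that do not care about the
distinction can catch a single type.
"""


class EmptyRegionError(ValueError):
    """An analysis plane or mask slice contains no lumen voxels."""


class InsufficientSamplesError(ValueError):
    """A least-squares fit has fewer sample points than basis terms.

    On coarse scans the inlet plane may hold too few voxels to constrain the
    requested polynomial surface; this is the per-frame signal of that
    failure mode.
    """


class DegenerateRayError(ValueError):
    """A wall-shear-stress ray found fewer lumen samples than the fit needs."""
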