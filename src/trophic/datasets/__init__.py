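"""Bundled example datasets.

Everything here is SYNTHETIC: small constructed tables used by the examples
and tests, not measured data.
"""

from importlib import resources

import pandas as pd

from trophic.tradeoff import TraitRecord, frame_to_records

__all__ = ["load_synthetic_isolate_traits"]


def load_synthetic_isolate_traits(as_records: bool = True) -> "list[TraitRecord] | pd.DataFrame":
    """Synthetic 11-strain trait table for the tradeoff analyses.

    A constructed stand-in for an isolate trait panel: 7 mixotrophs spanning a
    wide range of specific clearance rates (the chrysophyte is the fastest
    grazer and cannot grow phototrophically; the two *Florenciella* are the
    slowest grazers and the fastest-growing mixotrophs) plus 4 autotrophs with
    clearance 0 and low-light growth rates in the 0.25-0.42 d-1 range.  The
    rank structure was engineered so that the mixotroph-only and all-strain
    Spearman correlations between high-light growth and clearance rate match
    the published values (-0.85 and -0.74) at two decimals; the individual
    numbers are synthetic.
    """
    with resources.files(__package__).joinpath("synthetic_isolate_traits.csv").open() as fh:
        frame = pd.read_csv(fh)
    frame["is_mixotroph"] = frame["is_mixotroph"].astype(bool)
    if as_records:
        return frame_to_records(frame)
    return frame
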