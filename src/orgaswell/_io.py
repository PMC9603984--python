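"""CSV I/O with bit-exact float round-trips.

``%.17g`` on write guarantees every float64 can be recovered exactly, and
``float_precision="round_trip"`` on read makes the parser correctly rounding
(pandas' default fast parser can be off by one ulp). Together they back the
pipeline's byte-identical rerun contract.
"""

import pandas as pd


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip", **kwargs)
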