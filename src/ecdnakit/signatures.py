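"""SBS96 signature models: reference matrices, exposures, attribution.

The reference matrix R has one row per signature and 96 columns (one per
trinucleotide channel); rows are probability distributions over channels.
Per-sample exposures E give the activity of each signature in a sample.

Per-mutation attribution follows the likelihood rule used in pan-cancer
timing analyses: the probability that signature *s* generated a mutation in
channel *c* of sample *j* is

    P(s | c, j) = E_{j,s} R_{s,c} / sum_{s'} E_{j,s'} R_{s',c}

which is invariant to any positive rescaling of the sample's exposure
vector, so normalized and raw exposures give identical attributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .channels import CHANNELS, N_CHANNELS, channel_index
from .errors import DataError, FormatError, UnattributableMutationError


@dataclass
class SignatureModel:
    """Reference signatures (rows x 96) plus optional per-sample exposures."""

    names: tuple[str, ...]
    R: np.ndarray
    exposures: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape != (len(self.names), N_CHANNELS):
            raise FormatError(
                f"reference matrix must be {len(self.names)} x {N_CHANNELS}"
            )
        if np.any(self.R < 0):
            raise FormatError("reference matrix has negative entries")
        sums = self.R.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise FormatError("signature rows must sum to 1 (+- 1e-9)")
        if self.exposures is not None:
            if list(self.exposures.columns) != list(self.names):
                raise FormatError("exposure columns must match signature names")
            if (self.exposures.to_numpy() < 0).any():
                raise FormatError("exposures must be non-negative")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def exposure_vector(self, sample: str) -> np.ndarray:
        if self.exposures is None or sample not in self.exposures.index:
            raise DataError(f"no exposures for sample {sample!r}")
        return self.exposures.loc[sample].to_numpy(dtype=float)

    def with_exposures(self, exposures: pd.DataFrame) -> "SignatureModel":
        return SignatureModel(self.names, self.R, exposures)


def signature_posteriors(
    channel: int | str, sample: str, model: SignatureModel
) -> np.ndarray:
    """Posterior probability over signatures for one mutation's channel."""
    c = channel_index(channel) - 1
    e = model.exposure_vector(sample)
    lik = e * model.R[:, c]
    total = lik.sum()
    if total <= 0:
        raise UnattributableMutationError(
            f"channel {channel} in sample {sample}: zero total likelihood"
        )
    return lik / total


def most_likely_signature(
    channel: int | str, sample: str, model: SignatureModel
) -> str:
    """Argmax signature for a mutation; exact ties break to the lowest index."""
    post = signature_posteriors(channel, sample, model)
    return model.names[int(np.argmax(post))]


def build_catalogue(mutations: pd.DataFrame) -> pd.DataFrame:
    """96 x 2 pre/post mutation catalogue from timed mutations.

    ``mutations`` needs columns ``mutation_id``, ``channel`` (1..96 or
    string) and ``status`` in {"pre", "post"}; unclassified mutations must
    be excluded upstream. Column sums equal the pre and post counts.
    """
    cat = pd.DataFrame(
        0, index=pd.Index(range(1, N_CHANNELS + 1), name="channel"),
        columns=["pre", "post"], dtype=int,
    )
    if len(mutations) == 0:
        return cat
    if mutations["mutation_id"].duplicated().any():
        dups = mutations.loc[mutations["mutation_id"].duplicated(), "mutation_id"]
        raise FormatError(f"duplicate mutation ids: {sorted(set(dups))[:5]}")
    for row in mutations.itertuples():
        if row.status not in ("pre", "post"):
            raise FormatError(f"status {row.status!r} not in {{pre, post}}")
        cat.loc[channel_index(row.channel), row.status] += 1
    return cat


def channel_counts(channels) -> np.ndarray:
    """Length-96 count vector from an iterable of channels."""
    counts = np.zeros(N_CHANNELS, dtype=float)
    for ch in channels:
        counts[channel_index(ch) - 1] += 1
    return counts


def fit_exposures_nnls(
    counts_by_sample: pd.DataFrame, model: SignatureModel
) -> pd.DataFrame:
    """Naive per-sample exposures by non-negative least squares.

    ``counts_by_sample``: samples x 96 channel counts. Returns exposures
    normalized to sum to 1 per sample (attribution is scale-invariant, so
    normalization is cosmetic). Intended for synthetic self-containment;
    real analyses should supply externally fitted exposures.
    """
    if counts_by_sample.shape[1] != N_CHANNELS:
        raise FormatError(f"counts must have {N_CHANNELS} columns")
    rows = {}
    A = model.R.T  # 96 x S
    for sample, counts in counts_by_sample.iterrows():
        y = counts.to_numpy(dtype=float)
        total = y.sum()
        if total <= 0:
            rows[sample] = np.zeros(model.n_signatures)
            continue
        x, _ = nnls(A, y / total)
        s = x.sum()
        rows[sample] = x / s if s > 0 else x
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(model.names)
    ).rename_axis("sample")


# ---------------------------------------------------------------------------
# TSV adapters (signatures: rows = signatures, columns = channel strings;
# exposures: rows = samples, columns = signature names)

def write_signatures_tsv(model: SignatureModel, path) -> None:
    pd.DataFrame(model.R, index=list(model.names), columns=list(CHANNELS)).rename_axis(
        "signature"
    ).to_csv(path, sep="\t", float_format="%.10g")


def read_signatures_tsv(path) -> SignatureModel:
    """Adapter accepting any signatures x 96 TSV with channel-string header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(CHANNELS):
        raise FormatError(
            f"{path}: header must list the 96 channel strings in canonical order"
        )
    return SignatureModel(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def write_exposures_tsv(exposures: pd.DataFrame, path) -> None:
    exposures.rename_axis("sample").to_csv(path, sep="\t", float_format="%.10g")


def read_exposures_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
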