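"""Site frequency spectra: container, file dialects, folding, Poisson likelihood.

The central object is :class:`SFSpectrum`, a vector of counts of variant sites
indexed by derived (unfolded) or minor (folded) allele count in a sample of
``n`` haploid chromosomes.  Monomorphic classes (0 and n) are never stored.

Two on-disk dialects are supported:

``supplementary_line``
    Whitespace-separated numbers, unfolded, singletons first (the format used
    for published per-study SFS text tables).  ``n`` is the number of entries
    plus one.

``dadi_fs``
    The dadi frequency-spectrum format: a header line ``N folded/unfolded``,
    then ``N`` entries *including* the two monomorphic classes, and an
    optional mask line.  Read/write compatible for interoperability.

The Poisson random-field likelihood implemented here includes the
``-log(x_i!)`` constant, i.e. it is the full Poisson log-pmf summed over
entries.  This makes reported log-likelihoods directly comparable across
tools that report the full likelihood rather than a kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SFSpectrum",
    "read_sfs",
    "write_sfs",
    "fold_sfs",
    "poisson_loglik",
    "SFSParseError",
]


class SFSParseError(ValueError):
    """Raised when an SFS file cannot be parsed."""


@dataclass
class SFSpectrum:
    """A site frequency spectrum.

    Parameters
    ----------
    counts
        Counts of variant sites per allele-count class.  Length ``n - 1``
        (classes 1..n-1) if unfolded, ``n // 2`` (classes 1..n//2) if folded.
        Stored as floats because *expected* spectra are non-integer.
    n
        Haploid sample size (number of sampled chromosomes).
    folded
        Whether the spectrum is indexed by minor allele count.
    label
        Free text, e.g. ``"synonymous"``.
    """

    counts: np.ndarray
    n: int
    folded: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n < 2:
            raise ValueError(f"haploid sample size must be >= 2, got {self.n}")
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected_len = self.n // 2 if self.folded else self.n - 1
        if len(self.counts) != expected_len:
            raise ValueError(
                f"{'folded' if self.folded else 'unfolded'} spectrum with n={self.n} "
                f"must have {expected_len} entries, got {len(self.counts)}"
            )

    @property
    def num_segregating(self) -> float:
        return float(self.counts.sum())

    def validate_observed(self) -> None:
        """Check that counts are integer-valued, as observed data must be."""
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("observed spectrum has non-integer counts")

    def copy(self, **changes) -> "SFSpectrum":
        out = replace(self, **changes)
        out.counts = out.counts.copy()
        return out


def fold_sfs(sfs: SFSpectrum) -> SFSpectrum:
    """Fold an unfolded spectrum onto minor-allele-count classes.

    Entry ``i`` of the result is ``x_i + x_{n-i}`` for ``i < n/2`` and
    ``x_{n/2}`` for the central class when ``n`` is even.  Total count is
    conserved.  Folding an already-folded spectrum raises, to catch pipeline
    wiring errors.
    """
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n
    x = sfs.counts
    m = n // 2
    out = np.empty(m)
    for i in range(1, m + 1):
        if i < n - i:
            out[i - 1] = x[i - 1] + x[n - i - 1]
        else:  # central class, n even
            out[i - 1] = x[i - 1]
    return SFSpectrum(out, n=n, folded=True, label=sfs.label)


def read_sfs(path, dialect: str = "supplementary_line", label: str = "") -> SFSpectrum:
    """Read an SFS file.

    ``supplementary_line`` files are unfolded counts, singletons first;
    ``dadi_fs`` files carry their own sample size and folding flag.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "supplementary_line":
        values = []
        for lineno, line in enumerate(lines, start=1):
            for col, tok in enumerate(line.split(), start=1):
                try:
                    v = float(tok)
                except ValueError:
                    raise SFSParseError(
                        f"{path}: malformed token {tok!r} at line {lineno}, field {col}"
                    ) from None
                values.append(v)
        if not values:
            raise SFSParseError(f"{path}: empty SFS file")
        counts = np.array(values)
        if np.any(counts < 0):
            raise SFSParseError(f"{path}: negative count in SFS")
        return SFSpectrum(counts, n=len(counts) + 1, folded=False, label=label)
    elif dialect == "dadi_fs":
        return _read_dadi_fs(path, lines, label)
    raise ValueError(f"unknown SFS dialect: {dialect!r}")


def _read_dadi_fs(path: str, lines: list[str], label: str) -> SFSpectrum:
    content = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if len(content) < 2:
        raise SFSParseError(f"{path}: dadi fs file needs a header and a data line")
    header = content[0].split()
    try:
        n_entries = int(header[0])
    except (ValueError, IndexError):
        raise SFSParseError(f"{path}: bad dadi fs header {content[0]!r}") from None
    folded = len(header) > 1 and header[1].lower().startswith("folded")
    try:
        full = np.array([float(t) for t in content[1].split()])
    except ValueError:
        raise SFSParseError(f"{path}: malformed entry on dadi fs data line") from None
    if len(full) != n_entries:
        raise SFSParseError(
            f"{path}: header promises {n_entries} entries, found {len(full)}"
        )
    n = n_entries - 1
    if folded:
        counts = full[1 : n // 2 + 1]
        return SFSpectrum(counts, n=n, folded=True, label=label)
    counts = full[1:n]
    return SFSpectrum(counts, n=n, folded=False, label=label)


def write_sfs(sfs: SFSpectrum, path, dialect: str = "supplementary_line") -> None:
    """Write an SFS file in the requested dialect."""
    path = str(path)
    if dialect == "supplementary_line":
        if sfs.folded:
            raise ValueError("supplementary_line dialect stores unfolded spectra")
        with open(path, "w") as fh:
            fh.write(" ".join(f"{c:.17g}" for c in sfs.counts) + "\n")
    elif dialect == "dadi_fs":
        full = np.zeros(sfs.n + 1)
        if sfs.folded:
            full[1 : sfs.n // 2 + 1] = sfs.counts
            tag = "folded"
        else:
            full[1 : sfs.n] = sfs.counts
            tag = "unfolded"
        mask = np.ones(sfs.n + 1, dtype=int)
        mask[0] = mask[-1] = 0
        if sfs.folded:
            mask[sfs.n // 2 + 1 :] = 0
        with open(path, "w") as fh:
            fh.write(f"{sfs.n + 1} {tag}\n")
            fh.write(" ".join(f"{c:.17g}" for c in full) + "\n")
            fh.write(" ".join(str(m) for m in mask) + "\n")
    else:
        raise ValueError(f"unknown SFS dialect: {dialect!r}")


def poisson_loglik(observed: SFSpectrum, expected: SFSpectrum) -> float:
    """Full Poisson log-likelihood of ``observed`` given mean ``expected``.

    Returns ``sum_i [x_i log m_i - m_i - log(x_i!)]`` over all stored entries.
    An expected entry of zero with a positive observation yields ``-inf``
    (with a warning); zero-observed/zero-expected entries contribute 0.
    """
    if observed.folded != expected.folded:
        raise ValueError("folded status mismatch between observed and expected")
    if len(observed.counts) != len(expected.counts):
        raise ValueError(
            f"length mismatch: observed has {len(observed.counts)} entries, "
            f"expected has {len(expected.counts)}"
        )
    x = observed.counts
    m = expected.counts
    bad = (m <= 0) & (x > 0)
    if np.any(bad):
        warnings.warn(
            "expected SFS entry is zero where observations exist; "
            "log-likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    ok = m > 0
    return float(np.sum(x[ok] * np.log(m[ok]) - m[ok] - gammaln(x[ok] + 1.0)))
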