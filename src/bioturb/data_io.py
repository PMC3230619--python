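"""Reading, writing and synthesising tracer-profile matrices.

Observed profiles arrive as plain-text numeric tables (rows = sediment
layers from the interface down, columns = time points), in whatever
dialect the imaging pipeline produced: whitespace, tab or comma
delimited, with or without a header row or a depth-label column. One
tolerant reader handles all of them; the writer emits a deterministic
tab-separated form.

`generate_synthetic` forward-simulates the lattice model and optionally
applies binomial detection thinning, standing in for the imaging
experiment so that calibration can be exercised against data whose
generating parameters are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ProfileFormatError, ProfileParseError
from .model import ModelParams, SimConfig, simulate
from .profiles import ProfileSeries

__all__ = [
    "read_profile",
    "write_profile",
    "SyntheticDataset",
    "generate_synthetic",
]


def _tokenize(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        return line.split()
    return [tok.strip() for tok in line.split(delimiter)]


def _sniff_delimiter(lines: list[str]) -> str | None:
    """Pick the delimiter that splits the first data line into most fields."""
    sample = lines[0]
    best, best_n = None, len(sample.split())
    for cand in (",", "\t", ";"):
        n = len([t for t in sample.split(cand)])
        if cand in sample and n > 1 and n >= best_n:
            best, best_n = cand, n
    return best


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_profile(
    path: str | Path,
    *,
    delimiter: str | None = "auto",
    orientation: str = "auto",
    dt_min: float = 5.0,
    layer_height_mm: float = 0.073,
) -> ProfileSeries:
    """Read a tracer-profile matrix from a plain-text table.

    Parameters
    ----------
    delimiter : "auto", None or str
        "auto" sniffs among whitespace, comma, tab and semicolon; None
        forces whitespace splitting.
    orientation : "auto", "layers-rows" or "layers-cols"
        Profiles usually have many more layers than time points, so
        "auto" keeps rows as layers when rows >= columns and transposes
        otherwise.
    dt_min, layer_height_mm :
        Physical scales attached to the returned series (plain tables do
        not carry them).

    A leading header row and a leading non-numeric label column are
    detected and dropped. Non-numeric cells and ragged rows raise located
    errors.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw_lines)
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        return ProfileSeries(np.zeros((0, 0)), dt_min=dt_min, layer_height_mm=layer_height_mm)

    delim = _sniff_delimiter([ln for _, ln in lines]) if delimiter == "auto" else delimiter
    rows = [(lineno, _tokenize(ln, delim)) for lineno, ln in lines]

    # header row: any non-numeric token in the first line beyond a label column
    first_tokens = rows[0][1]
    if len(rows) > 1 and any(not _is_number(t) for t in first_tokens[1:]):
        rows = rows[1:]

    # label column: first token non-numeric on every remaining row
    has_label_col = all(not _is_number(toks[0]) for _, toks in rows if toks)
    if has_label_col:
        rows = [(lineno, toks[1:]) for lineno, toks in rows]

    widths = {len(toks) for _, toks in rows}
    if len(widths) > 1:
        raise ProfileFormatError(
            f"{path}: ragged rows (field counts {sorted(widths)})"
        )

    matrix = np.empty((len(rows), widths.pop()))
    for r, (lineno, toks) in enumerate(rows):
        for c, tok in enumerate(toks):
            try:
                val = float(tok)
            except ValueError:
                raise ProfileParseError(
                    f"{path}: non-numeric cell {tok!r} at line {lineno}, field {c + 1}",
                    row=lineno, column=c + 1,
                ) from None
            if val < 0:
                raise ProfileParseError(
                    f"{path}: negative count {val} at line {lineno}, field {c + 1}",
                    row=lineno, column=c + 1,
                )
            matrix[r, c] = val

    if orientation not in ("auto", "layers-rows", "layers-cols"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    if orientation == "layers-cols" or (
        orientation == "auto" and matrix.shape[0] < matrix.shape[1]
    ):
        matrix = matrix.T

    if np.all(matrix == np.floor(matrix)):
        matrix = matrix.astype(np.int64)
    return ProfileSeries(matrix, dt_min=dt_min, layer_height_mm=layer_height_mm)


def write_profile(series: ProfileSeries, path: str | Path) -> Path:
    """Write a profile series as a deterministic tab-separated table.

    Integer counts are written verbatim; real values with six decimal
    places. Rows are layers, interface first. Repeated writes of the same
    series are byte-identical.
    """
    path = Path(path)
    counts = np.asarray(series.counts)
    integral = np.issubdtype(counts.dtype, np.integer)
    with path.open("w") as fh:
        for row in counts:
            if integral:
                fh.write("\t".join(str(int(v)) for v in row))
            else:
                fh.write("\t".join(f"{v:.6f}" for v in row))
            fh.write("\n")
    return path


@dataclass(frozen=True)
class SyntheticDataset:
    """A synthetic observation plus the ground truth that generated it."""

    series: ProfileSeries
    true_params: ModelParams
    config: SimConfig
    p_detect: float | None = None


def generate_synthetic(
    params: ModelParams,
    config: SimConfig,
    *,
    p_detect: float | None = None,
) -> SyntheticDataset:
    """Forward-simulate an 'observed' dataset with known ground truth.

    Optionally thins every count binomially with detection probability
    ``p_detect`` in (0, 1], the simplest model of luminophores missed by
    the imaging pipeline. The thinning draws come from an RNG stream
    independent of the simulation's, so ``p_detect=None`` reproduces
    ``simulate`` exactly for the same config.
    """
    if p_detect is not None and not 0.0 < p_detect <= 1.0:
        raise ConfigurationError(f"p_detect must be in (0, 1], got {p_detect}")
    series = simulate(params, config)
    if p_detect is not None and p_detect < 1.0:
        rng = np.random.default_rng([config.seed, 0x5EED])
        thinned = rng.binomial(series.counts, p_detect)
        series = ProfileSeries(thinned, dt_min=series.dt_min,
                               layer_height_mm=series.layer_height_mm)
    return SyntheticDataset(series=series, true_params=params,
                            config=config, p_detect=p_detect)
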