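"""Fit the per-muscle Hermite-Rodriguez time-scale constants.

For each muscle, bisect the time scale λ so that the median frequency of
the order-mixed reference spectrum (the equal-weight average of the
order-1 and order-2 waveform periodograms, band-restricted to the
20-1000 Hz analysis band) hits the target group-mean MDF. The fitted
constants are frozen into ``myospect.synthetic_data`` as
``INTERFERENCE_LAMBDA_MS`` (interference-cohort targets) and
``MUAP_LAMBDA_MS`` (isolated-waveform targets).

Run from the repository root:

    python scripts/calibrate_lambdas.py
"""

from __future__ import annotations

import numpy as np

from myospect.core_io import PowerSpectrum
from myospect.spectral import median_frequency, periodogram
from myospect.synthetic_data import (
    INTERFERENCE_MDF_TARGETS_HZ,
    MUAP_MDF_TARGETS_HZ,
    hermite_rodriguez,
)

FS = 20_000.0
WINDOW_MS = 2000.0  # 0.5 Hz bins: fine enough that the discrete MDF is smooth
BAND = (20.0, 1000.0)


def mixed_mdf(lambda_ms: float) -> float:
    """MDF of the equal-amplitude order-1/order-2 reference spectrum.

    The generator draws waveform orders with equal probability and a
    shared amplitude distribution, so the reference mixture sums the raw
    (unnormalized) spectra: at equal amplitude the order-2 waveform
    carries about three times the energy of the order-1 waveform and
    weighs in accordingly.
    """
    spectra = [
        periodogram(hermite_rodriguez(order, 1.0, lambda_ms, window_ms=WINDOW_MS, fs=FS))
        for order in (1, 2)
    ]
    power = spectra[0].power + spectra[1].power
    return median_frequency(PowerSpectrum(spectra[0].freqs, power), band=BAND)


MUAP_WINDOW_MS = 75.0  # the population summary measures on 13.333 Hz bins
MUAP_LAMBDA_CV = 0.11  # between-waveform lambda jitter in the generator


def mean_order_mdf(lambda_mean_ms: float) -> float:
    """Expected per-waveform MDF of a generated MUAP population.

    The isolated-MUAP group summaries average each waveform's own MDF,
    measured on the 75 ms window's 13.333 Hz bin grid — whose round-up
    median convention biases individual values by up to one bin — so the
    calibration evaluates exactly that statistic: the equal-probability
    mean over the two orders and (by quantile quadrature) over the
    generator's lambda jitter.
    """
    from scipy.stats import norm

    quantiles = norm.ppf((np.arange(21) + 0.5) / 21)
    values = []
    for z in quantiles:
        lam = max(lambda_mean_ms * (1.0 + MUAP_LAMBDA_CV * z), 0.3 * lambda_mean_ms)
        for order in (1, 2):
            values.append(
                median_frequency(
                    periodogram(
                        hermite_rodriguez(order, 1.0, lam, window_ms=MUAP_WINDOW_MS, fs=FS)
                    )
                )
            )
    return float(np.mean(values))


def fit_lambda(target_hz: float, objective, lo: float = 0.5, hi: float = 8.0, tol: float = 1e-4) -> float:
    """Bisect λ (ms); MDF is monotone decreasing in λ."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if objective(mid) > target_hz:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def main() -> None:
    for name, targets, objective in (
        ("INTERFERENCE_LAMBDA_MS", INTERFERENCE_MDF_TARGETS_HZ, mixed_mdf),
        ("MUAP_LAMBDA_MS", MUAP_MDF_TARGETS_HZ, mean_order_mdf),
    ):
        print(f"{name} = {{")
        for muscle, target in targets.items():
            lam = fit_lambda(target, objective)
            print(f'    "{muscle}": {lam:.3f},   # target {target} Hz -> {objective(lam):.2f} Hz')
        print("}")


if __name__ == "__main__":
    main()
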