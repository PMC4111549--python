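"""Forward Wright-Fisher simulator: an oracle independent of the diffusion code.

Discrete generations, N diploids (2N chromosomes), infinite-sites mutation
influx of theta/2 new derived alleles per generation, genic selection with
fitness (1 + s) per derived copy, gamma = 4 N s. The expected sample SFS is
accumulated analytically (binomial sampling probabilities at the current
population frequencies), and Monte-Carlo standard errors come from batch
means over long batches.
"""

import numpy as np
from scipy import special


def wf_expected_sfs(
    gamma: float,
    n: int,
    theta: float,
    N: int = 200,
    burn_gens: int | None = None,
    n_batches: int = 25,
    batch_gens: int = 10000,
    spacing: int = 10,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium E[xi_i] for a sample of n chromosomes, with batch-mean SEs."""
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    s = gamma / (4 * N)
    per_gen = theta / 2.0
    if burn_gens is None:
        burn_gens = 10 * N
    coefs = np.exp([
        special.gammaln(n + 1) - special.gammaln(i + 1) - special.gammaln(n - i + 1)
        for i in range(1, n)
    ])
    ii = np.arange(1, n)

    freqs = np.zeros(0, dtype=np.int64)

    def step(freqs: np.ndarray) -> np.ndarray:
        if freqs.size:
            p = freqs / two_n
            p_sel = p * (1 + s) / (1 + p * s)
            freqs = rng.binomial(two_n, p_sel)
            freqs = freqs[(freqs > 0) & (freqs < two_n)]
        n_new = rng.poisson(per_gen)
        if n_new:
            freqs = np.concatenate([freqs, np.ones(n_new, dtype=np.int64)])
        return freqs

    for _ in range(burn_gens):
        freqs = step(freqs)

    batches = np.zeros((n_batches, n - 1))
    for b in range(n_batches):
        acc = np.zeros(n - 1)
        n_samples = 0
        for g in range(batch_gens):
            freqs = step(freqs)
            if g % spacing == 0:
                if freqs.size:
                    p = freqs / two_n
                    acc += (coefs[:, None] * p[None, :] ** ii[:, None]
                            * (1 - p)[None, :] ** (n - ii)[:, None]).sum(axis=1)
                n_samples += 1
        batches[b] = acc / n_samples
    mean = batches.mean(axis=0)
    se = batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return mean, se
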