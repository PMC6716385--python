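"""Model / Results objects over the mixture sampler.

`CriterionMixtureModel` holds one category's merged entry-by-item matrix and
the number of latent criterion groups; `fit()` runs the MCMC and returns a
`CriterionMixtureResults` carrying the posterior draws, label-switching
resolution, convergence diagnostics, posterior-mode group assignments and a
summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from . import model as _model
from .data import MergedMatrix, ResponseTable, merge_sessions
from .model import (AssignmentResult, ModelParameters, PosteriorSamples,
                    assign_groups, complete_loglik, fit_mcmc, relabel)


class CriterionMixtureModel:
    """Finite mixture of criterion groups for one category's binary matrix.

    Parameters
    ----------
    matrix : MergedMatrix
        Respondent-entry by item matrix (1 = yes, 0 = no, NaN = unknown).
    n_groups : int
        Number of latent criterion groups G (default 2).
    """

    def __init__(self, matrix: MergedMatrix, n_groups: int = 2):
        if n_groups < 2:
            raise ValueError("n_groups must be at least 2")
        self.matrix = matrix
        self.n_groups = int(n_groups)

    @classmethod
    def from_tables(
        cls,
        new_data: ResponseTable,
        archival_data: ResponseTable | None,
        category_id: str,
        n_groups: int = 2,
    ) -> "CriterionMixtureModel":
        """Build the model from long-format tables via session merging."""
        return cls(merge_sessions(new_data, archival_data, category_id), n_groups)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, category_id: str,
                       n_groups: int = 2) -> "CriterionMixtureModel":
        """Build from a long-format DataFrame (two-session data only)."""
        table = ResponseTable(df)
        return cls.from_tables(table, None, category_id, n_groups)

    def loglike(self, params: ModelParameters) -> float:
        return complete_loglik(params, self.matrix)

    def fit(
        self,
        n_chains: int = 3,
        n_iter: int = 10_000,
        n_burnin: int = 4_000,
        seed: int = 0,
        progress: bool = False,
    ) -> "CriterionMixtureResults":
        """Run the Metropolis-within-Gibbs sampler and wrap the draws."""
        samples = fit_mcmc(self.matrix, G=self.n_groups, n_chains=n_chains,
                           n_iter=n_iter, n_burnin=n_burnin, seed=seed,
                           progress=progress)
        return CriterionMixtureResults(self, samples)


@dataclass
class CriterionMixtureResults:
    """Posterior draws plus the summaries hanging off them."""

    model: CriterionMixtureModel
    samples: PosteriorSamples
    _assignment: AssignmentResult | None = field(default=None, repr=False)

    @property
    def relabeled(self) -> bool:
        return self.samples.relabeled

    def relabel(self) -> "CriterionMixtureResults":
        """Return results with label switching resolved (no-op if done)."""
        if self.samples.relabeled:
            return self
        return CriterionMixtureResults(self.model, relabel(self.samples))

    def to_inference_data(self) -> az.InferenceData:
        s = self.samples
        return az.from_dict(
            posterior={
                "pi": s.pi, "beta": s.beta, "theta": s.theta,
                "mu": s.mu, "alpha": s.alpha,
            },
            dims={"pi": ["group"], "beta": ["group", "item"],
                  "theta": ["entry"], "mu": ["group"], "alpha": ["group"]},
            coords={"group": np.arange(s.n_groups),
                    "item": self.model.matrix.items,
                    "entry": self.model.matrix.entry_index["entry_id"].tolist()},
        )

    def diagnostics(self) -> pd.DataFrame:
        """Split R-hat and effective sample size per continuous scalar."""
        return convergence_diagnostics(self.samples, idata=self.to_inference_data())

    def assign_groups(self) -> AssignmentResult:
        if self._assignment is None:
            self._assignment = assign_groups(self.samples)
        return self._assignment

    def assignment_frame(self) -> pd.DataFrame:
        """Assignments joined with the entry index (1-based group labels)."""
        a = self.assign_groups()
        out = self.model.matrix.entry_index.copy()
        out["modal_group"] = a.modal_group + 1
        for g in range(self.samples.n_groups):
            out[f"prob_group{g + 1}"] = a.prob[:, g]
        out["tie"] = a.tie_flag
        return out

    def posterior_mean(self, name: str) -> np.ndarray:
        """Posterior mean of ``pi``/``beta``/``theta``/``mu``/``alpha`` pooled over chains."""
        arr = getattr(self.samples, name)
        return arr.reshape(-1, *arr.shape[2:]).mean(axis=0)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval for group-level parameters."""
        if not self.samples.relabeled:
            raise ValueError("relabel the results before summarizing groups")
        rows = []
        s = self.samples
        for name in ("pi", "mu", "alpha"):
            arr = getattr(s, name).reshape(-1, s.n_groups)
            for g in range(s.n_groups):
                rows.append(self._summary_row(f"{name}[{g + 1}]", arr[:, g]))
        beta = s.beta.reshape(-1, s.n_groups, s.n_items)
        for g in range(s.n_groups):
            for i, item in enumerate(self.model.matrix.items):
                rows.append(self._summary_row(f"beta[{g + 1},{item}]", beta[:, g, i]))
        return pd.DataFrame(rows).set_index("parameter")

    @staticmethod
    def _summary_row(name: str, draws: np.ndarray) -> dict:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return {"parameter": name, "mean": draws.mean(), "sd": draws.std(ddof=1),
                "hdi_2.5%": lo, "hdi_97.5%": hi}

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> None:
        save_samples(self.samples, directory, self.model.matrix)

    @classmethod
    def load(cls, directory) -> "CriterionMixtureResults":
        samples, matrix = load_samples(directory)
        return cls(CriterionMixtureModel(matrix, samples.n_groups), samples)


def convergence_diagnostics(
    s: PosteriorSamples, idata: az.InferenceData | None = None
) -> pd.DataFrame:
    """Split potential-scale-reduction and ESS for every continuous scalar.

    Requires at least two relabeled chains.  Parameters whose pooled draws
    are constant are flagged ``degenerate`` with NaN statistics instead of a
    division by zero.
    """
    if s.n_chains < 2:
        raise ValueError("convergence diagnostics need at least 2 chains")
    if not s.relabeled:
        raise ValueError("relabel the samples before computing diagnostics")
    if idata is None:
        idata = az.from_dict(posterior={
            "pi": s.pi, "beta": s.beta, "theta": s.theta,
            "mu": s.mu, "alpha": s.alpha,
        })
    rows = []
    rhat = az.rhat(idata, method="split")
    ess = az.ess(idata)
    for name in ("pi", "mu", "alpha", "beta", "theta"):
        draws = getattr(s, name)
        flat = draws.reshape(s.n_chains, s.n_draws, -1)
        r = np.asarray(rhat[name]).reshape(-1)
        e = np.asarray(ess[name]).reshape(-1)
        for k in range(flat.shape[2]):
            scalar = flat[:, :, k]
            degenerate = bool(np.ptp(scalar) == 0)
            rows.append({
                "parameter": f"{name}[{k}]",
                "rhat": np.nan if degenerate else float(r[k]),
                "ess": np.nan if degenerate else float(e[k]),
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows).set_index("parameter")


# --------------------------------------------------------------------------
# on-disk format: JSON metadata + one flat CSV of draws per chain
# --------------------------------------------------------------------------

def _draw_columns(s: PosteriorSamples) -> list[str]:
    G, I, P = s.n_groups, s.n_items, s.n_entries
    cols = [f"pi.{g + 1}" for g in range(G)]
    cols += [f"beta.{g + 1}.{i + 1}" for g in range(G) for i in range(I)]
    cols += [f"theta.{p + 1}" for p in range(P)]
    cols += [f"mu.{g + 1}" for g in range(G)]
    cols += [f"alpha.{g + 1}" for g in range(G)]
    cols += [f"z.{p + 1}" for p in range(P)]
    return cols


def save_samples(s: PosteriorSamples, directory, matrix: MergedMatrix | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_chains": s.n_chains, "n_iter": s.n_iter, "n_burnin": s.n_burnin,
        "n_draws": s.n_draws, "n_groups": s.n_groups, "n_entries": s.n_entries,
        "n_items": s.n_items, "seed": s.seed, "relabeled": s.relabeled,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    if matrix is not None:
        from .data import write_matrix
        write_matrix(matrix, d / "matrix.csv")
    for c in range(s.n_chains):
        block = np.concatenate([
            s.pi[c], s.beta[c].reshape(s.n_draws, -1), s.theta[c],
            s.mu[c], s.alpha[c], s.z[c].astype(float),
        ], axis=1)
        pd.DataFrame(block, columns=_draw_columns(s)).to_csv(
            d / f"chain{c + 1}.csv", index=False)


def load_samples(directory) -> tuple[PosteriorSamples, MergedMatrix]:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    from .data import read_matrix
    matrix = read_matrix(d / "matrix.csv")
    C, D = meta["n_chains"], meta["n_draws"]
    G, P, I = meta["n_groups"], meta["n_entries"], meta["n_items"]
    s = PosteriorSamples(
        pi=np.empty((C, D, G)), z=np.empty((C, D, P), dtype=np.int16),
        beta=np.empty((C, D, G, I)), theta=np.empty((C, D, P)),
        mu=np.empty((C, D, G)), alpha=np.empty((C, D, G)),
        n_chains=C, n_iter=meta["n_iter"], n_burnin=meta["n_burnin"],
        seed=meta["seed"], relabeled=meta["relabeled"],
    )
    for c in range(C):
        df = pd.read_csv(d / f"chain{c + 1}.csv")
        arr = df.to_numpy()
        k = 0
        s.pi[c] = arr[:, k:k + G]; k += G
        s.beta[c] = arr[:, k:k + G * I].reshape(D, G, I); k += G * I
        s.theta[c] = arr[:, k:k + P]; k += P
        s.mu[c] = arr[:, k:k + G]; k += G
        s.alpha[c] = arr[:, k:k + G]; k += G
        s.z[c] = arr[:, k:k + P].astype(np.int16)
    return s, matrix
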