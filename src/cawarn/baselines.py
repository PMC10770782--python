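"""Conventional classifiers behind one uniform interface.

A comparison zoo at default settings (logistic regression, k-NN, decision
tree, SVM, Gaussian naive Bayes, MLP, random forest, and an alternative
boosting library).  These exist for demo comparisons only; the pipeline's
own classifier lives in :mod:`cawarn.model`.
"""

from __future__ import annotations

from cawarn.errors import ConfigError


def make_baseline(name: str, seed: int = 0):
    """Instantiate a named baseline classifier with default settings."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from sklearn.ensemble import RandomForestClassifier

    zoo = {
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=seed),
        "KNN": lambda: KNeighborsClassifier(),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "SVM": lambda: SVC(probability=True, random_state=seed),
        "NB": lambda: GaussianNB(),
        "MLP": lambda: MLPClassifier(max_iter=500, random_state=seed),
        "RF": lambda: RandomForestClassifier(random_state=seed),
    }
    if name == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, eval_metric="logloss")
    if name not in zoo:
        raise ConfigError(f"unknown baseline {name!r}; choose from {sorted(zoo) + ['XGB']}")
    return zoo[name]()
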