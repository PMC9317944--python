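# Classifier presets, one block per experiment/test/region combination.
#
# Backend mapping (recorded here because the parameter names constrain but do
# not fully determine the library call):
#   MLP  -> sklearn MLPClassifier: a single hidden layer of H logistic
#           (sigmoid) units, plain SGD with constant learning rate L and
#           momentum M, trained for N epochs with early stopping disabled,
#           random_state = S.  Features are standardized beforehand.
#   SVM  -> sklearn SVC(kernel='rbf', C=C, gamma=G).  Features standardized.
#   KNN  -> sklearn KNeighborsClassifier(n_neighbors=k, metric=distance).
#           Features rescaled to [0, 1] (min-max), matching the default
#           attribute normalization of common KNN implementations.
#   MNLR -> sklearn LogisticRegression (multinomial) with L2 ridge strength
#           R, i.e. C = 1/R.  Features standardized.
exp1_face:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 5000, S: 0}
  SVM: {C: 1000.0, G: 0.1, kernel: rbf}
  KNN: {k: 1, distance: euclidean}
  MNLR: {R: 1.0e-08}
exp1_eyes:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 5000, S: 0}
  SVM: {C: 1000.0, G: 0.001, kernel: rbf}
  KNN: {k: 1, distance: euclidean}
  MNLR: {R: 1.0e-08}
exp1_mouth:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 5000, S: 0}
  SVM: {C: 1000.0, G: 0.01, kernel: rbf}
  KNN: {k: 1, distance: euclidean}
  MNLR: {R: 1.0e-08}
exp2_test1_eyes:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 500, S: 2}
  SVM: {C: 1000.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: manhattan}
  MNLR: {R: 1.0e-08}
exp2_test1_mouth:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 2000, S: 37}
  SVM: {C: 1000.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: manhattan}
  MNLR: {R: 1.0e-08}
exp2_test2_eyes:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 1000, S: 87}
  SVM: {C: 10.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: manhattan}
  MNLR: {R: 1.0e-08}
exp2_test2_mouth:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 500, S: 7}
  SVM: {C: 10.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: manhattan}
  MNLR: {R: 1.0e-08}
exp3_test1_eyes:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 1000, S: 18}
  SVM: {C: 10.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: manhattan}
  MNLR: {R: 1.0e-08}
exp3_test1_mouth:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 7000, S: 25}
  SVM: {C: 1000.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: manhattan}
  MNLR: {R: 1.0e-08}
exp3_test2_eyes:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 4000, S: 18}
  SVM: {C: 10.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: manhattan}
  MNLR: {R: 1.0e-08}
exp3_test2_mouth:
  MLP: {L: 0.2045, M: 0.1909, H: 59, N: 7000, S: 25}
  SVM: {C: 10.0, G: 1.0, kernel: rbf}
  KNN: {k: 1, distance: euclidean}
  MNLR: {R: 1.0e-08}
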