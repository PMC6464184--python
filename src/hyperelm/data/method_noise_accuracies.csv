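method,database,condition,accuracy
IPCA,polyu,pure,95.53
IPCA,polyu,gaussian,94.03
IPCA,polyu,saltpepper,94.4
IPCA,polyu,speckle,94.23
IPCA,casia,pure,93.67
IPCA,casia,gaussian,92.33
IPCA,casia,saltpepper,93.33
IPCA,casia,speckle,92.17
MPCA,polyu,pure,97.97
MPCA,polyu,gaussian,96.83
MPCA,polyu,saltpepper,97.07
MPCA,polyu,speckle,96.67
MPCA,casia,pure,96.5
MPCA,casia,gaussian,96.16
MPCA,casia,saltpepper,96.33
MPCA,casia,speckle,95.83
IDWT,polyu,pure,96.6
IDWT,polyu,gaussian,71.2
IDWT,polyu,saltpepper,61.07
IDWT,polyu,speckle,71.87
IDWT,casia,pure,94.0
IDWT,casia,gaussian,65.67
IDWT,casia,saltpepper,58.5
IDWT,casia,speckle,65.33
MDWT,polyu,pure,98.0
MDWT,polyu,gaussian,97.46
MDWT,polyu,saltpepper,97.37
MDWT,polyu,speckle,96.97
MDWT,casia,pure,96.67
MDWT,casia,gaussian,96.16
MDWT,casia,saltpepper,95.83
MDWT,casia,speckle,95.5
QPCA,polyu,pure,98.83
QPCA,polyu,gaussian,98.6
QPCA,polyu,saltpepper,97.9
QPCA,polyu,speckle,97.9
QPCA,casia,pure,96.67
QPCA,casia,gaussian,96.33
QPCA,casia,saltpepper,96.17
QPCA,casia,speckle,95.67
MPELM,polyu,pure,99.53
MPELM,polyu,gaussian,98.8
MPELM,polyu,saltpepper,98.87
MPELM,polyu,speckle,98.63
MPELM,casia,pure,90.0
MPELM,casia,gaussian,84.67
MPELM,casia,saltpepper,88.0
MPELM,casia,speckle,85.0
TELM,polyu,pure,99.95
TELM,polyu,gaussian,99.0
TELM,polyu,saltpepper,99.17
TELM,polyu,speckle,99.1
TELM,casia,pure,96.83
TELM,casia,gaussian,94.83
TELM,casia,saltpepper,96.0
TELM,casia,speckle,93.5
HELM,polyu,pure,100
HELM,polyu,gaussian,99.8
HELM,polyu,saltpepper,99.7
HELM,polyu,speckle,99.67
HELM,casia,pure,98.5
HELM,casia,gaussian,98.0
HELM,casia,saltpepper,97.83
HELM,casia,speckle,97.67
PCA+HELM,polyu,pure,100
PCA+HELM,polyu,gaussian,99.93
PCA+HELM,polyu,saltpepper,99.83
PCA+HELM,polyu,speckle,99.9
PCA+HELM,casia,pure,98.5
PCA+HELM,casia,gaussian,98.17
PCA+HELM,casia,saltpepper,98.0
PCA+HELM,casia,speckle,97.83
LBP+HELM,polyu,pure,100
LBP+HELM,polyu,gaussian,93.7
LBP+HELM,polyu,saltpepper,91.9
LBP+HELM,polyu,speckle,90.43
LBP+HELM,casia,pure,99.83
LBP+HELM,casia,gaussian,93.17
LBP+HELM,casia,saltpepper,90.83
LBP+HELM,casia,speckle,89.5
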