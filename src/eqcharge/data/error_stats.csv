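# Default per-element Gaussian parameters of the charge-model prediction
# errors, in electrons: mu is the mean signed error, sigma the standard
# deviation of the fitted normal distribution. These are the shipped
# defaults for the error-statistics-based equilibration schemes; models
# trained on other data should supply their own file in this format.
symbol,mu,sigma
C,3.77e-5,1.54e-2
H,-2.98e-4,8.98e-3
O,-1.97e-4,1.11e-2
N,-2.83e-4,2.21e-2
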