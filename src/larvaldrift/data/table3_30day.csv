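,Santiago,Maio,Boavista,Sal,Sao Nicolau,Ilheu Raso,Santa Luzia,Sao Vincente,Santo Antao
Santiago,—,3.50E-04,1.40E-04,4.30E-05,7.90E-04,1.80E-04,4.50E-04,9.90E-05,1.10E-04
Maio,4.70E-03,—,2.00E-05,2.00E-05,3.80E-04,9.70E-05,2.20E-04,5.90E-05,5.00E-05
Boavista,6.20E-04,3.60E-04,—,2.70E-04,7.80E-04,9.70E-05,2.70E-04,7.90E-05,1.10E-04
Sal,3.70E-04,1.70E-04,7.50E-04,—,2.10E-03,1.80E-04,8.10E-04,4.40E-04,3.10E-04
Sao Nicolau,6.60E-04,1.20E-04,2.00E-04,1.20E-04,—,1.90E-03,2.10E-03,7.70E-04,8.00E-04
Ilheu Raso,6.80E-05,6.40E-06,1.10E-05,1.20E-05,1.60E-04,—,6.80E-04,2.00E-04,2.40E-04
Santa Luzia,3.40E-05,4.90E-06,2.80E-05,2.50E-05,2.60E-04,1.90E-04,—,1.60E-03,8.70E-04
Sao Vincente,1.70E-05,4.10E-06,1.60E-05,1.60E-05,9.70E-05,1.00E-04,1.10E-03,—,2.30E-03
Santo Antao,4.90E-06,2.30E-06,2.30E-05,5.50E-06,2.00E-04,1.00E-04,7.40E-04,1.30E-03,—
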