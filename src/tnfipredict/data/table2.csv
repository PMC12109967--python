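patient_id,drug,drug_class,das28_m0,das28_m3,prediction,evolution
P01,GOL,antibody,5.09,4.47,-,-
P02,GOL,antibody,4.50,2.00,+,+
P03,ADA,antibody,5.40,3.10,+,+
P04,GOL,antibody,4.58,2.35,+,+
P05,ADA,antibody,3.78,1.04,+,+
P06,ADA,antibody,4.79,1.21,+,+
P07,ADA,antibody,7.10,5.16,-,-
P08,GOL,antibody,4.15,2.94,+,+
P09,IFX,antibody,4.39,2.61,+,+
P10,ADA,antibody,6.02,5.37,-,-
P11,IFX,antibody,5.60,3.17,-,-
P12,ADA,antibody,2.62,1.40,+,+
P13,GOL,antibody,3.78,4.16,+,-
P14,ADA,antibody,4.92,3.04,+,+
P15,ADA,antibody,5.58,3.15,+,+
P16,ETA,soluble_receptor,3.72,1.73,-,+
P17,ETA,soluble_receptor,5.88,2.50,-,+
P18,ETA,soluble_receptor,4.55,2.25,-,+
P19,ETA,soluble_receptor,4.64,2.56,-,+
P20,ETA,soluble_receptor,5.12,2.59,+?,+
P21,ETA,soluble_receptor,3.55,2.69,-,+
P22,ETA,soluble_receptor,4.63,2.82,+?,+
P23,ETA,soluble_receptor,6.03,1.40,-,+
P24,ETA,soluble_receptor,3.97,1.50,+,+
P25,ETA,soluble_receptor,4.18,2.12,+,+
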