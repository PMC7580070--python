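topic_id,label,super_topic,clinical,women_specific
t001,pregnancy outcomes,pregnancy,True,True
t002,antenatal care,pregnancy,True,True
t003,oral contraceptives,contraception,True,True
t004,breast cancer screening,breast cancer,True,True
t005,myocardial infarction,cardiology,True,False
t006,hypertension treatment,cardiology,True,False
t007,depression,psychiatry,True,False
t008,schizophrenia,psychiatry,True,False
t009,lung cancer,oncology,True,False
t010,chemotherapy trials,oncology,True,False
t011,hospital administration,healthcare management,False,False
t012,medical training,medical profession,False,False
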