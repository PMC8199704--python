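site,sex,model,beta,gamma,eta
stomach,male,ERR,0.21,-0.3,-1.4
stomach,female,ERR,0.48,-0.3,-1.4
colon,male,ERR,0.63,-0.3,-1.4
colon,female,ERR,0.43,-0.3,-1.4
liver,male,ERR,0.32,-0.3,-1.4
liver,female,ERR,0.32,-0.3,-1.4
lung,male,ERR,0.32,-0.3,-1.4
lung,female,ERR,1.40,-0.3,-1.4
prostate,male,ERR,0.12,-0.3,-1.4
uterus,female,ERR,0.055,-0.3,-1.4
ovary,female,ERR,0.38,-0.3,-1.4
bladder,male,ERR,0.50,-0.3,-1.4
bladder,female,ERR,1.65,-0.3,-1.4
breast,female,ERR,0.51,-0.3,-1.4
thyroid,male,ERR,0.53,-0.3,-1.4
thyroid,female,ERR,1.05,-0.3,-1.4
other,male,ERR,0.27,-0.3,-1.4
other,female,ERR,0.45,-0.3,-1.4
stomach,male,EAR,4.9,-0.41,2.8
stomach,female,EAR,4.9,-0.41,2.8
colon,male,EAR,3.2,-0.41,2.8
colon,female,EAR,1.6,-0.41,2.8
liver,male,EAR,2.2,-0.41,2.8
liver,female,EAR,1.0,-0.41,2.8
lung,male,EAR,2.3,-0.41,5.2
lung,female,EAR,3.4,-0.41,5.2
prostate,male,EAR,0.11,-0.41,2.8
uterus,female,EAR,1.2,-0.41,2.8
ovary,female,EAR,0.70,-0.41,2.8
bladder,male,EAR,1.2,-0.41,2.8
bladder,female,EAR,0.75,-0.41,2.8
breast,female,EAR,9.4,-0.41,2.8
other,male,EAR,6.2,-0.41,2.8
other,female,EAR,4.8,-0.41,2.8
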