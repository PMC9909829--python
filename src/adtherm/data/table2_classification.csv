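true_class,tumor_type,classified_benign,classified_malignant
benign,Adenoma,4,0
benign,Benign epithelial/adnexal cyst/tumor,4,1
benign,Benign melanoma,1,0
benign,Lipoma,18,3
benign,Papilloma,1,0
benign,Perineal adenoma,2,0
benign,Plasmacytoma,1,0
benign,Reactive lymph node,2,0
benign,Sebaceous adenoma,2,1
benign,Sebaceous hamartoma,1,0
benign,Sebaceous hyperplasia,1,0
malignant,Adenocarcinoma,0,3
malignant,Cutaneous hemangiosarcoma,0,3
malignant,Lymphoma,2,8
malignant,Mast cell tumor,0,5
malignant,Metastatic lymph node (hemangiosarcoma),0,1
malignant,Metastatic lymph node (melanoma),0,1
malignant,Osteosarcoma,0,1
malignant,Soft tissue sarcoma,0,1
malignant,Undifferentiated neoplasia,0,2
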